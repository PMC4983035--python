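"""Sliding-window detection of clustered acidic residues (Cter calling).

The operational criterion for a clustered-acidic C-terminal (Cter) domain is
a stretch of ``window`` consecutive residues (default 10) in which at least
``min_fraction`` (default 0.8, inclusive) are acidic (Asp or Glu). The scan
is restricted to the C-terminal ``tail_len`` residues (default 50; pass
``"all"`` to scan the whole sequence), since the domain of interest sits at
the carboxy terminus.

All positions are 1-based inclusive on the full (unrestricted) sequence.
``X`` residues never count as acidic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError, ValidationError
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class AcidicScanParams:
    """Parameters of the windowed acidity scan.

    window : length of the sliding window, in residues.
    min_fraction : minimum acidic fraction for a hit; the comparison is
        inclusive, so window 10 with min_fraction 0.8 requires >= 8 acidic
        residues.
    acidic_set : residues counted as acidic (default D and E).
    tail_len : length of the C-terminal search region, or "all".
    """

    window: int = 10
    min_fraction: float = 0.8
    acidic_set: frozenset[str] = DEFAULT_ACIDIC
    tail_len: int | str = 50

    def __post_init__(self) -> None:
        if self.window < 1:
            raise InputError("window must be a positive integer")
        if not (0.0 < self.min_fraction <= 1.0):
            raise InputError("min_fraction must lie in (0, 1]")
        if self.tail_len != "all":
            if not isinstance(self.tail_len, int) or self.tail_len < 1:
                raise InputError('tail_len must be a positive integer or "all"')
            if self.window > self.tail_len:
                raise InputError("window must not exceed tail_len")
        object.__setattr__(self, "acidic_set", frozenset(self.acidic_set))


@dataclass(frozen=True)
class AcidicWindowHit:
    """One window meeting the acidity criterion (1-based inclusive coords)."""

    seq_id: str
    start: int
    end: int
    acidic_count: int
    fraction: float


@dataclass(frozen=True)
class CterCall:
    """Per-sequence Cter classification.

    ``positive`` iff at least one window hit exists in the search region.
    ``best_hit`` maximises the acidic fraction; ties go to the rightmost
    (most C-terminal) start.
    """

    seq_id: str
    positive: bool
    n_hits: int
    best_hit: AcidicWindowHit | None = field(default=None)


def scan_acidic_windows(seq: ProteinRecord,
                        params: AcidicScanParams | None = None,
                        ) -> list[AcidicWindowHit]:
    """All windows in the C-terminal search region meeting the criterion.

    Returns hits in position order. A sequence shorter than the window
    returns an empty list with a logged warning.
    """
    params = params or AcidicScanParams()
    residues = seq.residues
    L = len(residues)
    w = params.window
    if L < w:
        logger.warning("sequence %r (length %d) shorter than window %d",
                       seq.id, L, w)
        return []
    if params.tail_len == "all":
        region_start = 1
    else:
        region_start = max(1, L - int(params.tail_len) + 1)
    acidic = params.acidic_set
    hits: list[AcidicWindowHit] = []
    # rolling count over the search region
    count = sum(1 for c in residues[region_start - 1:region_start - 1 + w]
                if c in acidic)
    min_count = params.min_fraction * w
    start = region_start
    while start + w - 1 <= L:
        if count >= min_count - 1e-12:
            hits.append(AcidicWindowHit(
                seq_id=seq.id, start=start, end=start + w - 1,
                acidic_count=count, fraction=count / w,
            ))
        if start + w - 1 < L:
            count -= residues[start - 1] in acidic
            count += residues[start + w - 1] in acidic
        start += 1
    return hits


def call_cter(seq: ProteinRecord,
              params: AcidicScanParams | None = None) -> CterCall:
    """Classify one sequence as Cter-positive or -negative."""
    params = params or AcidicScanParams()
    hits = scan_acidic_windows(seq, params)
    if not hits:
        return CterCall(seq_id=seq.id, positive=False, n_hits=0, best_hit=None)
    best = max(hits, key=lambda h: (h.fraction, h.start))
    return CterCall(seq_id=seq.id, positive=True, n_hits=len(hits), best_hit=best)


def classify_family(records: list[ProteinRecord],
                    params: AcidicScanParams | None = None) -> pd.DataFrame:
    """Cter calls for a family, one row per record.

    Columns: seq_id, positive, n_hits, best_start, best_end, best_fraction.
    Raises :class:`ValidationError` on duplicate ids.
    """
    params = params or AcidicScanParams()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sequence ids: {dupes}")
    rows = []
    for rec in records:
        call = call_cter(rec, params)
        rows.append({
            "seq_id": call.seq_id,
            "positive": call.positive,
            "n_hits": call.n_hits,
            "best_start": call.best_hit.start if call.best_hit else pd.NA,
            "best_end": call.best_hit.end if call.best_hit else pd.NA,
            "best_fraction": call.best_hit.fraction if call.best_hit else pd.NA,
        })
    table = pd.DataFrame(
        rows, columns=["seq_id", "positive", "n_hits",
                       "best_start", "best_end", "best_fraction"])
    n_pos = int(table["positive"].sum()) if len(table) else 0
    logger.info("Cter classification: %d positive / %d total", n_pos, len(table))
    return table
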