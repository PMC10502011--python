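"""RIP-like mutation index.

Repeat-induced point mutation (RIP) and RIP-like genome defenses convert
cytosines to thymines in repetitive DNA.  In *Microbotryum*-like genomes the
targeted context is the TCG trinucleotide (CGA on the reverse complement), so
a region that has experienced RIP is depleted in TCG/CGA and enriched in the
TTG/CAA products.  The index used here is the ratio

    t = (#TTG + #CAA) / (#TCG + #CGA - #overlap)

of product over remaining target sites, divided by the same ratio ``n``
computed on non-target contexts ([A,C,G]TG + CA[C,G,T] over [A,C,G]CG +
CG[C,G,T] - [A,C,G]CG[C,G,T]) to control for base composition.  The
normalized index ``t/n - 1`` is positive where RIP-like mutation exceeds the
compositional expectation.

All motifs are counted on the forward strand with one-base sliding
(overlapping occurrences count); reverse-strand sites are represented by
their reverse-complement motifs, which are already part of each formula.
The subtracted overlap motif is the tetranucleotide containing both a
forward TCG and a reverse-strand CGA site (TCGA by default, configurable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .core import Interval, TECopy

_RE_CACHE: dict[str, re.Pattern] = {}


def _count(seq: str, pattern: str) -> int:
    """Overlapping occurrences of a character-class motif pattern."""
    rx = _RE_CACHE.get(pattern)
    if rx is None:
        rx = re.compile(f"(?=(?:{pattern}))")
        _RE_CACHE[pattern] = rx
    return sum(1 for _ in rx.finditer(seq))


@dataclass
class RIPWindowStats:
    """Site counts and the normalized RIP index for one window."""

    interval: Interval
    product_sites: int
    target_sites: int
    control_product: int
    control_target: int

    @property
    def t(self) -> Optional[float]:
        if self.target_sites <= 0:
            return None
        return self.product_sites / self.target_sites

    @property
    def n(self) -> Optional[float]:
        if self.control_target <= 0:
            return None
        return self.control_product / self.control_target

    @property
    def normalized_index(self) -> Optional[float]:
        t, n = self.t, self.n
        if t is None or n is None or n == 0:
            return None
        return t / n - 1.0


def count_rip_sites(sequence: str, overlap_motif: str = "TCGA") -> tuple[int, int, int, int]:
    """Count (product, target, control_product, control_target) sites.

    N bases never match any motif; matching is case-insensitive.
    """
    seq = sequence.upper()
    product = _count(seq, "TTG") + _count(seq, "CAA")
    target = _count(seq, "TCG") + _count(seq, "CGA") - _count(seq, overlap_motif)
    control_product = _count(seq, "[ACG]TG") + _count(seq, "CA[CGT]")
    control_target = (
        _count(seq, "[ACG]CG") + _count(seq, "CG[CGT]") - _count(seq, "[ACG]CG[CGT]")
    )
    return product, target, control_product, control_target


def rip_stats(sequence: str, interval: Interval, overlap_motif: str = "TCGA") -> RIPWindowStats:
    p, t, cp, ct = count_rip_sites(sequence, overlap_motif)
    return RIPWindowStats(interval, p, t, cp, ct)


def rip_window_track(contig_id: str, sequence: str, width: int = 1000,
                     overlap_motif: str = "TCGA") -> list[RIPWindowStats]:
    """Per-window RIP statistics over non-overlapping windows.

    The final partial window is computed on its actual length; windows where
    a denominator vanishes carry a missing index.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out: list[RIPWindowStats] = []
    for start in range(0, len(sequence), width):
        end = min(start + width, len(sequence))
        out.append(
            rip_stats(sequence[start:end], Interval(contig_id, start, end), overlap_motif)
        )
    return out


def track_to_frame(track: Iterable[RIPWindowStats]) -> pd.DataFrame:
    rows = []
    for w in track:
        rows.append(
            {
                "contig": w.interval.contig_id,
                "start": w.interval.start,
                "end": w.interval.end,
                "product_sites": w.product_sites,
                "target_sites": w.target_sites,
                "control_product": w.control_product,
                "control_target": w.control_target,
                "t": w.t,
                "n": w.n,
                "normalized_index": w.normalized_index,
            }
        )
    return pd.DataFrame(rows)


def smooth_values(values: list[Optional[float]], window: int, step: int) -> list[Optional[float]]:
    """Running mean over ``window`` consecutive entries every ``step`` entries
    (missing values excluded from each mean)."""
    out: list[Optional[float]] = []
    for start in range(0, len(values), step):
        chunk = [v for v in values[start:start + window] if v is not None]
        out.append(sum(chunk) / len(chunk) if chunk else None)
    return out


def rip_of_copies(copies: Iterable[TECopy], sequences: dict[str, str],
                  group_key=None, overlap_motif: str = "TCGA") -> pd.DataFrame:
    """Normalized RIP index per TE copy (computed on the copy's own
    sequence) and, when ``group_key`` is given, the per-group mean.

    ``sequences`` maps contig id to sequence.  Copies with undefined indices
    are carried with a missing value and excluded from group means.
    """
    rows = []
    for copy in copies:
        iv = copy.interval
        seq = sequences[iv.contig_id][iv.start:iv.end]
        stats = rip_stats(seq, iv, overlap_motif)
        rows.append(
            {
                "copy_id": copy.copy_id,
                "compartment": copy.compartment,
                "category": copy.categories[0],
                "group": group_key(copy) if group_key is not None else None,
                "normalized_index": stats.normalized_index,
            }
        )
    return pd.DataFrame(rows)


def group_mean_index(per_copy: pd.DataFrame, by: str = "group") -> pd.Series:
    """Mean normalized index per group, missing when all values are missing."""
    return per_copy.groupby(by, dropna=False)["normalized_index"].mean()
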