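"""Shared domain types for genome-compartment and transposable-element analyses.

All genomic coordinates are 0-based, half-open ``[start, end)``.  GFF3 and
other 1-based closed formats are converted at the I/O boundary (:mod:`tedyn.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

#: Compartment labels, lowest to highest painting precedence.  A base is
#: labelled by the highest-precedence feature covering it.
COMPARTMENT_PRECEDENCE = (
    "autosome",
    "PAR",
    "NRR",          # NRR strata use labels "NRR:<stratum>"
    "centromere",
    "subtelomere",
    "telomere",
)


class ValidationError(ValueError):
    """A structural invariant of the input data is violated."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Contig:
    """A contig sequence over the DNA alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    interval: Interval
    gene_id: str
    stratum_label: Optional[str] = None


@dataclass
class TECopy:
    """An annotated transposable-element copy.

    ``categories`` holds one or more superfamily labels (multiple labels only
    through the annotation tie rule); ``ltr5``/``ltr3`` are the long-terminal
    repeats of LTR retroelements, nested within ``interval``.
    """

    copy_id: str
    interval: Interval
    categories: list[str] = field(default_factory=lambda: ["unclassified"])
    family_id: Optional[str] = None
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError(f"copy {self.copy_id}: empty category list")
        for ltr in (self.ltr5, self.ltr3):
            if ltr is not None and not self.interval.contains(ltr):
                raise ValidationError(
                    f"copy {self.copy_id}: LTR {ltr} not nested in {self.interval}"
                )
        if self.ltr5 is not None and self.ltr3 is not None:
            if self.ltr5.overlaps(self.ltr3):
                raise ValidationError(f"copy {self.copy_id}: overlapping LTRs")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class HitRecord:
    """One similarity hit of a TE-candidate query against a genome.

    ``identity`` and ``gapless_query_coverage`` are fractions in [0, 1]
    (percent identity from tabular hit files is converted on read).
    """

    query_id: str
    subject_contig: str
    identity: float
    aln_length: int
    gapless_query_coverage: float
    evalue: float
    subject_interval: Interval

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(f"identity {self.identity} outside [0, 1]")
        cov = self.gapless_query_coverage
        if cov == cov and not (0.0 <= cov <= 1.0):  # NaN allowed (unknown)
            raise ValidationError(f"coverage {cov} outside [0, 1]")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")


@dataclass
class StatResult:
    """A generic hypothesis-test result (Wilcoxon V, ANOVA F, Pearson r, ...)."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    adjusted_p: Optional[float] = None
    note: Optional[str] = None


# ---------------------------------------------------------------------------
# interval arithmetic helpers

def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) pairs into disjoint pairs."""
    pairs = sorted(pairs)
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def covered_bases(pairs: Iterable[tuple[int, int]], window: tuple[int, int]) -> int:
    """Bases of ``window`` covered by the union of ``pairs``."""
    ws, we = window
    total = 0
    for s, e in merge_intervals(pairs):
        lo, hi = max(s, ws), min(e, we)
        if lo < hi:
            total += hi - lo
    return total


class CompartmentMap:
    """Disjoint labelled intervals covering every base of every contig.

    Built by painting features in precedence order (telomere > subtelomere >
    centromere > NRR stratum > PAR > autosome); the effective label of a base
    is the last one painted over it.
    """

    def __init__(self, contig_lengths: dict[str, int]):
        self.contig_lengths = dict(contig_lengths)
        # per contig: label array represented as sorted breakpoint segments
        self._segments: dict[str, list[tuple[int, int, str]]] = {
            cid: [(0, ln, "autosome")] for cid, ln in self.contig_lengths.items()
        }

    def paint(self, contig_id: str, start: int, end: int, label: str) -> None:
        if contig_id not in self._segments:
            raise ValidationError(f"unknown contig {contig_id}")
        ln = self.contig_lengths[contig_id]
        if not (0 <= start < end <= ln):
            raise ValidationError(
                f"paint [{start}, {end}) outside contig {contig_id} of length {ln}"
            )
        out: list[tuple[int, int, str]] = []
        for s, e, lab in self._segments[contig_id]:
            if e <= start or s >= end:
                out.append((s, e, lab))
                continue
            if s < start:
                out.append((s, start, lab))
            if e > end:
                out.append((end, e, lab))
        out.append((start, end, label))
        out.sort()
        # coalesce adjacent same-label segments
        merged: list[tuple[int, int, str]] = []
        for seg in out:
            if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
                merged[-1] = (merged[-1][0], seg[1], seg[2])
            else:
                merged.append(seg)
        self._segments[contig_id] = merged

    def segments(self, contig_id: Optional[str] = None) -> Iterator[tuple[str, int, int, str]]:
        ids = [contig_id] if contig_id is not None else sorted(self._segments)
        for cid in ids:
            for s, e, lab in self._segments[cid]:
                yield cid, s, e, lab

    def label_at(self, contig_id: str, pos: int) -> str:
        for s, e, lab in self._segments[contig_id]:
            if s <= pos < e:
                return lab
        raise ValidationError(f"position {pos} outside contig {contig_id}")

    def label_bases(self) -> dict[str, int]:
        """Total bases per effective label."""
        out: dict[str, int] = {}
        for _, s, e, lab in self.segments():
            out[lab] = out.get(lab, 0) + (e - s)
        return out

    def intervals_with_label(self, predicate) -> list[Interval]:
        return [
            Interval(cid, s, e)
            for cid, s, e, lab in self.segments()
            if predicate(lab)
        ]

    def validate(self) -> None:
        """Check exact, non-overlapping coverage of every contig."""
        for cid, ln in self.contig_lengths.items():
            pos = 0
            for s, e, _ in self._segments[cid]:
                if s != pos:
                    raise ValidationError(f"coverage gap at {cid}:{pos}")
                pos = e
            if pos != ln:
                raise ValidationError(f"coverage ends at {cid}:{pos}, expected {ln}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"contig": cid, "start": s, "end": e, "label": lab}
            for cid, s, e, lab in self.segments()
        ]
        return pd.DataFrame(rows, columns=["contig", "start", "end", "label"])


@dataclass
class GenomeAssembly:
    """A haploid assembly: contigs plus gene, TE and auxiliary feature layers."""

    contigs: dict[str, Contig]
    genes: list[GeneFeature] = field(default_factory=list)
    te_copies: list[TECopy] = field(default_factory=list)
    bed_layers: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_genes: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen_genes:
                raise ValidationError(f"duplicate gene id {gene.gene_id}")
            seen_genes.add(gene.gene_id)
            self._check_interval(gene.interval, f"gene {gene.gene_id}")
        for copy in self.te_copies:
            self._check_interval(copy.interval, f"TE copy {copy.copy_id}")
        for name, ivs in self.bed_layers.items():
            for iv in ivs:
                self._check_interval(iv, f"{name} interval")

    def _check_interval(self, iv: Interval, what: str) -> None:
        contig = self.contigs.get(iv.contig_id)
        if contig is None:
            raise ValidationError(f"{what}: unknown contig {iv.contig_id}")
        if iv.end > contig.length:
            raise ValidationError(
                f"{what}: end {iv.end} beyond contig {iv.contig_id} "
                f"length {contig.length}"
            )

    def sequence_of(self, iv: Interval) -> str:
        seq = self.contigs[iv.contig_id].sequence[iv.start:iv.end]
        if iv.strand == "-":
            return reverse_complement(seq)
        return seq

    @property
    def genome_size(self) -> int:
        return sum(c.length for c in self.contigs.values())


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
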