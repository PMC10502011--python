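"""TE-candidate filtering, majority-rule annotation and discard rules.

The repeat criterion retains a candidate query only when it matched at least
``min_matches`` sequences in the same genome at identity >= 0.8, alignment
length > 100 bp and gapless query coverage >= 0.8.  For qualifying queries,
further matches passing the same identity/length/coverage thresholds are
retained when their e-value falls below a threshold — either a fixed value
or the 25th percentile of the e-value distribution of qualifying queries'
hits ("q25" mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import FilterConfig
from .core import GeneFeature, HitRecord, Interval, TECopy

#: Superfamily vocabulary for annotation evidence labels.
SUPERFAMILIES = ("Copia", "Ty3", "Helitron", "TIR")

#: Genomic-length bands of putatively intact (full-length) copies.
INTACT_LENGTH_BANDS = {
    "Copia": (5000, 7500),
    "Ty3": (5000, 7500),
    "Helitron": (5000, 11000),
}


@dataclass
class AnnotationEvidence:
    """Per-copy annotation labels from the independent evidence sources."""

    copy_id: str
    dna_hit_label: Optional[str] = None
    protein_hit_label: Optional[str] = None
    domain_label: Optional[str] = None
    detector_label: Optional[str] = None

    def labels(self) -> list[Optional[str]]:
        return [
            self.dna_hit_label,
            self.protein_hit_label,
            self.domain_label,
            self.detector_label,
        ]


@dataclass
class FilterResult:
    retained: list[HitRecord]
    evalue_threshold: float
    #: whether the threshold was derived from the data (q25) or fixed
    threshold_mode: str


def _passes_primary(hit: HitRecord, cfg: FilterConfig) -> bool:
    cov = hit.gapless_query_coverage
    return (
        hit.identity >= cfg.min_identity
        and hit.aln_length > cfg.min_length_bp
        and cov == cov  # NaN coverage never qualifies
        and cov >= cfg.min_coverage
    )


def filter_hits(hits: Sequence[HitRecord], cfg: Optional[FilterConfig] = None) -> FilterResult:
    """Apply the repeat criterion and secondary e-value retention.

    Returns the union of primary-qualifying hits and secondary-retained hits
    of qualifying queries, in input order.  For each qualifying query the
    ``min_matches`` hits with the smallest e-values among those passing the
    identity/length/coverage thresholds are kept unconditionally; additional
    threshold-passing hits are kept only when their e-value is at most the
    secondary threshold.  Queries failing the repeat criterion contribute
    nothing.
    """
    cfg = cfg or FilterConfig()
    if not hits:
        warnings.warn("filter_hits: empty hit table", stacklevel=2)
        return FilterResult([], math.nan, "empty")

    by_query: dict[str, list[tuple[int, HitRecord]]] = {}
    for idx, hit in enumerate(hits):
        by_query.setdefault(hit.query_id, []).append((idx, hit))

    qualifying = {
        q: rows
        for q, rows in by_query.items()
        if sum(_passes_primary(h, cfg) for _, h in rows) >= cfg.min_matches
    }

    if cfg.evalue_threshold == "q25":
        pool = [h.evalue for rows in qualifying.values() for _, h in rows]
        threshold = float(np.quantile(pool, 0.25)) if pool else math.nan
        mode = "q25"
    else:
        threshold = float(cfg.evalue_threshold)
        mode = "fixed"

    keep: set[int] = set()
    for rows in qualifying.values():
        primary = sorted(
            (pair for pair in rows if _passes_primary(pair[1], cfg)),
            key=lambda pair: (pair[1].evalue, pair[0]),
        )
        for idx, _ in primary[: cfg.min_matches]:
            keep.add(idx)
        for idx, hit in primary[cfg.min_matches:]:
            if hit.evalue <= threshold:
                keep.add(idx)

    retained = [hit for idx, hit in enumerate(hits) if idx in keep]
    return FilterResult(retained, threshold, mode)


def majority_annotation(evidence: AnnotationEvidence) -> list[str]:
    """Most frequent non-null evidence label; ties keep all tied labels in
    lexicographic order (a multiple annotation); no label at all yields
    ["unclassified"]."""
    counts: dict[str, int] = {}
    for label in evidence.labels():
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    if not counts:
        return ["unclassified"]
    best = max(counts.values())
    return sorted(lab for lab, c in counts.items() if c == best)


def apply_discard_rules(
    copies: Iterable[TECopy],
    genes: Iterable[GeneFeature],
    rrna_mito_hits: Iterable[HitRecord] = (),
    rrna_mito_evalue: float = 1e-10,
) -> list[TECopy]:
    """Drop unclassified copies overlapping genes (>= 1 bp) and any copy
    overlapping an rRNA/ribosomal/mitochondrial hit at e-value <= 1e-10."""
    gene_ivs = [g.interval for g in genes]
    contaminant_ivs = [
        h.subject_interval for h in rrna_mito_hits if h.evalue <= rrna_mito_evalue
    ]
    out: list[TECopy] = []
    for copy in copies:
        if copy.categories == ["unclassified"] and any(
            copy.interval.overlaps(iv) for iv in gene_ivs
        ):
            continue
        if any(copy.interval.overlaps(iv) for iv in contaminant_ivs):
            continue
        out.append(copy)
    return out


def intact_fraction(copies: Sequence[TECopy], superfamily: str) -> Optional[float]:
    """Fraction of copies of ``superfamily`` whose genomic footprint falls in
    the intact-length band; missing (None) when there are no copies."""
    band = INTACT_LENGTH_BANDS.get(superfamily)
    if band is None:
        raise KeyError(f"no intact-length band defined for {superfamily!r}")
    group = [c for c in copies if superfamily in c.categories]
    if not group:
        return None
    lo, hi = band
    return sum(lo <= c.length <= hi for c in group) / len(group)


def hits_to_copies(hits: Iterable[HitRecord], prefix: str = "te") -> list[TECopy]:
    """Materialize retained hits as genomic TE copies (one per subject
    interval, deduplicated on exact coordinates)."""
    seen: set[tuple[str, int, int]] = set()
    copies: list[TECopy] = []
    for i, hit in enumerate(hits):
        iv = hit.subject_interval
        key = (iv.contig_id, iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        copies.append(
            TECopy(copy_id=f"{prefix}_{i:06d}", interval=iv, family_id=hit.query_id)
        )
    return copies
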