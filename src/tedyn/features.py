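"""Telomere/centromere detection, compartment partitioning, window densities
and the margin-accumulation test.

The genome is partitioned into the compartments used throughout the
analysis: autosome, pseudo-autosomal region (PAR), non-recombining-region
(NRR) strata, centromere, subtelomere and telomere, with painting precedence
telomere > subtelomere > centromere > NRR stratum > PAR > autosome so that
every base carries exactly one effective label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import FeatureConfig
from .core import (
    CompartmentMap,
    Contig,
    GeneFeature,
    GenomeAssembly,
    Interval,
    TECopy,
    ValidationError,
    covered_bases,
    merge_intervals,
)


@dataclass
class WindowTrack:
    """Fixed-width window values along one contig."""

    contig_id: str
    width: int
    step: int
    starts: list[int]
    ends: list[int]
    values: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig_id,
                "start": self.starts,
                "end": self.ends,
                "value": self.values,
            }
        )


@dataclass
class MarginTestResult:
    """Outcome of comparing the NRR-flanking PAR window with autosomal windows."""

    side: str
    eligible: bool
    reason: Optional[str] = None
    margin_value: Optional[float] = None
    autosome_window_values: Optional[list[float]] = None
    probability: Optional[float] = None


# ---------------------------------------------------------------------------
# telomeres and centromeres

def _count_overlapping(seq: str, motif: str) -> int:
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def detect_telomeres(contig: Contig, cfg: Optional[FeatureConfig] = None) -> list[Interval]:
    """Telomeres: a contig end whose terminal 100 bp contain at least five
    (overlapping) occurrences of TTAGGG or of its reverse complement CCCTAA."""
    cfg = cfg or FeatureConfig()
    term = cfg.telomere_terminal_bp
    if contig.length < term:
        return []
    from .core import reverse_complement

    motifs = (cfg.telomere_motif.upper(), reverse_complement(cfg.telomere_motif.upper()))
    seq = contig.sequence.upper()
    out: list[Interval] = []
    head = seq[:term]
    if any(_count_overlapping(head, m) >= cfg.telomere_min_count for m in motifs):
        out.append(Interval(contig.id, 0, term))
    tail = seq[-term:]
    if any(_count_overlapping(tail, m) >= cfg.telomere_min_count for m in motifs):
        iv = Interval(contig.id, contig.length - term, contig.length)
        if not out or not out[0].overlaps(iv):
            out.append(iv)
    return out


def detect_centromere(
    contig: Contig,
    repeat_hits: Sequence[Interval],
    genes: Sequence[GeneFeature],
    cfg: Optional[FeatureConfig] = None,
) -> Optional[Interval]:
    """Predicted centromere: the largest stretch of centromeric-repeat hits
    (hits separated by at most ``merge_gap`` merged), extended outward in
    1-kb steps while the gene-covered fraction of each candidate extension
    window stays below 0.25.  Contigs of at most 20 kb return None."""
    cfg = cfg or FeatureConfig()
    if contig.length <= cfg.centromere_min_contig_bp:
        return None
    pairs = [
        (iv.start, iv.end) for iv in repeat_hits if iv.contig_id == contig.id
    ]
    if not pairs:
        return None
    # merge hits whose gap is <= merge_gap into stretches
    pairs.sort()
    stretches: list[tuple[int, int]] = []
    for s, e in pairs:
        if stretches and s - stretches[-1][1] <= cfg.centromere_merge_gap_bp:
            stretches[-1] = (stretches[-1][0], max(stretches[-1][1], e))
        else:
            stretches.append((s, e))
    start, end = max(stretches, key=lambda p: p[1] - p[0])

    gene_pairs = [
        (g.interval.start, g.interval.end)
        for g in genes
        if g.interval.contig_id == contig.id
    ]
    step = cfg.centromere_step_bp

    def density(win_start: int, win_end: int) -> float:
        if win_end <= win_start:
            return 1.0
        return covered_bases(gene_pairs, (win_start, win_end)) / (win_end - win_start)

    while start > 0:
        cand = max(0, start - step)
        if density(cand, start) < cfg.centromere_max_gene_density:
            start = cand
        else:
            break
    while end < contig.length:
        cand = min(contig.length, end + step)
        if density(end, cand) < cfg.centromere_max_gene_density:
            end = cand
        else:
            break
    return Interval(contig.id, start, end)


# ---------------------------------------------------------------------------
# compartment map

def build_compartment_map(
    assembly: GenomeAssembly,
    nrr: Sequence[tuple[Interval, str]] = (),
    par: Sequence[Interval] = (),
    centromeres: Sequence[Interval] = (),
    telomeres: Sequence[Interval] = (),
    cfg: Optional[FeatureConfig] = None,
) -> CompartmentMap:
    """Paint compartments in precedence order; every base gets exactly one
    effective label.  ``nrr`` supplies (interval, stratum-label) pairs; the
    stratum label is stored as "NRR:<stratum>".  Subtelomeres are derived as
    the 20 kb adjacent to each telomere."""
    cfg = cfg or FeatureConfig()
    for iv, _ in nrr:
        for piv in par:
            if iv.overlaps(piv):
                raise ValidationError(f"NRR {iv} overlaps PAR {piv}")
    cmap = CompartmentMap({cid: c.length for cid, c in assembly.contigs.items()})
    for iv in par:
        cmap.paint(iv.contig_id, iv.start, iv.end, "PAR")
    for iv, stratum in nrr:
        cmap.paint(iv.contig_id, iv.start, iv.end, f"NRR:{stratum}")
    for iv in centromeres:
        cmap.paint(iv.contig_id, iv.start, iv.end, "centromere")
    for iv in telomeres:
        length = assembly.contigs[iv.contig_id].length
        if iv.start == 0:
            sub_end = min(iv.end + cfg.subtelomere_bp, length)
            if iv.end < sub_end:
                cmap.paint(iv.contig_id, iv.end, sub_end, "subtelomere")
        else:
            sub_start = max(iv.start - cfg.subtelomere_bp, 0)
            if sub_start < iv.start:
                cmap.paint(iv.contig_id, sub_start, iv.start, "subtelomere")
    for iv in telomeres:
        cmap.paint(iv.contig_id, iv.start, iv.end, "telomere")
    cmap.validate()
    return cmap


# ---------------------------------------------------------------------------
# densities and TE content

def window_density(
    features: Sequence[Interval],
    contig: Contig,
    width: int,
    step: Optional[int] = None,
) -> WindowTrack:
    """Per-window fraction of bases covered by the (merged) feature set;
    the final partial window is included with its own width."""
    if width <= 0 or (step is not None and step <= 0):
        raise ValueError("width and step must be positive")
    step = step or width
    pairs = merge_intervals(
        (iv.start, iv.end) for iv in features if iv.contig_id == contig.id
    )
    starts, ends, values = [], [], []
    for s in range(0, contig.length, step):
        e = min(s + width, contig.length)
        starts.append(s)
        ends.append(e)
        values.append(covered_bases(pairs, (s, e)) / (e - s))
        if e == contig.length:
            break
    return WindowTrack(contig.id, width, step, starts, ends, values)


def compartment_te_content(
    copies: Iterable[TECopy], cmap: CompartmentMap
) -> pd.DataFrame:
    """Percent of base pairs occupied by (merged) TEs per compartment label;
    TE intervals straddling a boundary are apportioned to each side."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for copy in copies:
        by_contig.setdefault(copy.interval.contig_id, []).append(
            (copy.interval.start, copy.interval.end)
        )
    te_bases: dict[str, int] = {}
    label_bases = cmap.label_bases()
    for cid, pairs in by_contig.items():
        merged = merge_intervals(pairs)
        for _, s, e, lab in cmap.segments(cid):
            te_bases[lab] = te_bases.get(lab, 0) + covered_bases(merged, (s, e))
    rows = []
    for lab in sorted(label_bases):
        total = label_bases[lab]
        rows.append(
            {
                "compartment": lab,
                "bases": total,
                "te_bases": te_bases.get(lab, 0),
                "te_percent": 100.0 * te_bases.get(lab, 0) / total if total else None,
            }
        )
    return pd.DataFrame(rows)


def aggregate_nrr_percent(content: pd.DataFrame) -> Optional[float]:
    """Pooled TE percent over all NRR strata of a compartment table."""
    nrr = content[content["compartment"].str.startswith("NRR:")]
    if nrr.empty or nrr["bases"].sum() == 0:
        return None
    return 100.0 * nrr["te_bases"].sum() / nrr["bases"].sum()


# ---------------------------------------------------------------------------
# margin accumulation test

def _te_fraction(pairs: list[tuple[int, int]], window: tuple[int, int]) -> float:
    return covered_bases(pairs, window) / (window[1] - window[0])


def margin_accumulation_test(
    cmap: CompartmentMap,
    copies: Iterable[TECopy],
    centromeres: Sequence[Interval] = (),
    cfg: Optional[FeatureConfig] = None,
) -> list[MarginTestResult]:
    """For each PAR side adjacent to the NRR, compare the TE fraction of the
    100-kb PAR window flanking the NRR boundary against the distribution of
    TE fractions in 100-kb non-overlapping autosomal windows (laid from each
    eligible segment start, at least 100 kb from centromeres, subtelomeres
    and telomeres excluded; trailing partial windows discarded).

    The reported probability is the fraction of autosomal windows with a TE
    fraction at least as large as the margin window's.  Sides with PAR
    < 100 kb, or genomes with fewer than 30 autosomal windows, are flagged
    ineligible rather than computed.
    """
    cfg = cfg or FeatureConfig()
    w = cfg.margin_window_bp

    te_pairs: dict[str, list[tuple[int, int]]] = {}
    for copy in copies:
        te_pairs.setdefault(copy.interval.contig_id, []).append(
            (copy.interval.start, copy.interval.end)
        )
    te_pairs = {cid: merge_intervals(p) for cid, p in te_pairs.items()}

    # autosomal windows
    cen_by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in centromeres:
        cen_by_contig.setdefault(iv.contig_id, []).append((iv.start, iv.end))
    auto_values: list[float] = []
    for cid in sorted(cmap.contig_lengths):
        segments = [
            (s, e) for c, s, e, lab in cmap.segments(cid) if lab == "autosome"
        ]
        buffered = [
            (max(0, s - cfg.margin_centromere_buffer_bp),
             e + cfg.margin_centromere_buffer_bp)
            for s, e in cen_by_contig.get(cid, [])
        ]
        for s, e in segments:
            # subtract centromere buffers from the segment
            keep = [(s, e)]
            for bs, be in buffered:
                nxt = []
                for ks, ke in keep:
                    if be <= ks or bs >= ke:
                        nxt.append((ks, ke))
                        continue
                    if ks < bs:
                        nxt.append((ks, bs))
                    if be < ke:
                        nxt.append((be, ke))
                keep = nxt
            for ks, ke in keep:
                for ws in range(ks, ke - w + 1, w):
                    auto_values.append(
                        _te_fraction(te_pairs.get(cid, []), (ws, ws + w))
                    )

    results: list[MarginTestResult] = []
    sides = _nrr_flanking_par_windows(cmap, w)
    for side, window in sides:
        if window is None:
            results.append(
                MarginTestResult(side, eligible=False, reason=f"PAR < {w} bp")
            )
            continue
        if len(auto_values) < cfg.margin_min_windows:
            results.append(
                MarginTestResult(
                    side, eligible=False,
                    reason=f"autosomal windows < {cfg.margin_min_windows}",
                )
            )
            continue
        cid, ws, we = window
        margin = _te_fraction(te_pairs.get(cid, []), (ws, we))
        prob = sum(v >= margin for v in auto_values) / len(auto_values)
        results.append(
            MarginTestResult(
                side, eligible=True, margin_value=margin,
                autosome_window_values=list(auto_values), probability=prob,
            )
        )
    return results


def _nrr_flanking_par_windows(cmap: CompartmentMap, w: int):
    """Locate, per mating-type contig, the 100-kb PAR window on each side of
    the NRR; a side whose PAR is shorter than ``w`` yields None."""
    sides = []
    for cid in sorted(cmap.contig_lengths):
        segs = list(cmap.segments(cid))
        nrr_spans = [(s, e) for _, s, e, lab in segs if lab.startswith("NRR:")]
        par_spans = [(s, e) for _, s, e, lab in segs if lab == "PAR"]
        if not nrr_spans:
            continue
        nrr_lo = min(s for s, _ in nrr_spans)
        nrr_hi = max(e for _, e in nrr_spans)
        left = [(s, e) for s, e in par_spans if e <= nrr_lo]
        right = [(s, e) for s, e in par_spans if s >= nrr_hi]
        left_len = sum(e - s for s, e in left)
        right_len = sum(e - s for s, e in right)
        if left:
            edge = max(e for _, e in left)
            sides.append(
                (f"{cid}:left",
                 (cid, edge - w, edge) if left_len >= w else None)
            )
        if right:
            edge = min(s for s, _ in right)
            sides.append(
                (f"{cid}:right",
                 (cid, edge, edge + w) if right_len >= w else None)
            )
    return sides
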