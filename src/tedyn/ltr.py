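"""LTR divergence, burst-versus-gene-conversion testing, and pair statistics.

An LTR retrotransposon carries two long terminal repeats that are identical
at insertion and then diverge independently, so the 5'-3' LTR divergence
within a copy (N2) dates the insertion.  The 5'-LTR of a new copy is also
identical to its progenitor's 5'-LTR at transposition, so the 5'-5'
divergence between a copy and its most similar copy (N1) dates the
transposition event.  Copies born in a transposition burst satisfy
N1 ~ N2 (a cloud around the first bisector); gene conversion overwrites the
5'-LTR of an old copy with a donor's, producing small N1 with large N2
(bottom-right outliers).  The null spread around the bisector is modelled by
drawing both coordinates from a Poisson distribution with rate equal to the
observed mean N2, and outliers are called by a two-sided tail test on
D = N2 - N1 against the simulated D distribution.

Substitution counts use the gamma-corrected Kimura two-parameter distance

    d = (a/2) [(1 - 2P - Q)^(-1/a) - 1] + (a/4) [(1 - 2Q)^(-1/a) - 1]

(P transitions, Q transversions per aligned ungapped site, a the gamma shape
parameter) multiplied by the number of aligned sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .config import LtrConfig
from .core import Interval, StatResult, TECopy

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance undefined: the alignment is at or beyond K2P saturation."""


@dataclass
class DistanceResult:
    P: float
    Q: float
    alpha: float
    d: float
    L: int

    @property
    def substitutions(self) -> float:
        return self.d * self.L


@dataclass
class LtrSeqs:
    """The LTR sequences of one retroelement copy, analysis-side unit."""

    copy_id: str
    ltr5: str
    ltr3: Optional[str] = None
    compartment: Optional[str] = None
    species: Optional[str] = None


@dataclass
class LTRPairRecord:
    copy_id: str
    closest_copy_id: Optional[str]
    N1: Optional[float]
    N2: Optional[float]
    compartment: Optional[str] = None
    closest_compartment: Optional[str] = None
    species: Optional[str] = None
    classification: str = "unpaired"


@dataclass
class PoissonNull:
    lambda_hat: float
    m: int
    alpha_level: float
    upper_D_threshold: float
    lower_D_threshold: float
    seed: int


@dataclass
class BurstCluster:
    members: list[str]
    compartments: list[Optional[str]]

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# orientation

def orient_ltrs(
    copy: TECopy, ltr_intervals: Sequence[Interval], coding_strand: Optional[str]
) -> tuple[Optional[TECopy], str]:
    """Assign 5'/3' LTRs from coding-sequence orientation.

    Returns (copy-with-LTRs, status).  On the + strand the leftmost LTR is
    the 5' one; on the - strand the rightmost.  Copies with more than two
    LTRs are excluded as nested; copies without a coding orientation cannot
    be polarized and are excluded (tallied by the caller).
    """
    if len(ltr_intervals) > 2:
        return None, "nested"
    if coding_strand not in ("+", "-"):
        return None, "unoriented"
    ordered = sorted(ltr_intervals, key=lambda iv: iv.start)
    if len(ordered) == 1:
        ltr5 = ordered[0]
        copy.ltr5 = ltr5
        copy.ltr3 = None
    elif coding_strand == "+":
        copy.ltr5, copy.ltr3 = ordered[0], ordered[1]
    else:
        copy.ltr5, copy.ltr3 = ordered[1], ordered[0]
    copy.interval = Interval(
        copy.interval.contig_id, copy.interval.start, copy.interval.end, coding_strand
    )
    return copy, "oriented"


# ---------------------------------------------------------------------------
# alignment and distances

def make_aligner(cfg: Optional[LtrConfig] = None) -> Align.PairwiseAligner:
    cfg = cfg or LtrConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match_score
    aligner.mismatch_score = cfg.mismatch_score
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    return aligner


def align_pair(seq_a: str, seq_b: str, cfg: Optional[LtrConfig] = None) -> tuple[str, str]:
    """Global pairwise alignment; returns the two gapped strings."""
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires non-empty sequences")
    aligner = make_aligner(cfg)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1])


def count_pq(gapped_a: str, gapped_b: str) -> tuple[float, float, int]:
    """Transition/transversion proportions and gap-free aligned length."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings differ in length")
    transitions = transversions = L = 0
    for x, y in zip(gapped_a.upper(), gapped_b.upper()):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        L += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            transitions += 1
        else:
            transversions += 1
    if L == 0:
        raise ValueError("no gap-free aligned sites")
    return transitions / L, transversions / L, L


def k2p_gamma_distance(P: float, Q: float, alpha: float) -> float:
    """Gamma-corrected K2P distance per site; as alpha -> infinity this
    converges to the plain K2P value -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated alignment (P={P:.3f}, Q={Q:.3f})")
    # expm1 keeps precision for large alpha, where the bracket is ~ -ln(w)/alpha
    term1 = (alpha / 2.0) * math.expm1(-math.log(w1) / alpha)
    term2 = (alpha / 4.0) * math.expm1(-math.log(w2) / alpha)
    return term1 + term2


def gamma_k2p(alignment: tuple[str, str], alpha: float = 1.0) -> DistanceResult:
    """Distance of an aligned pair (two gapped strings) under gamma-K2P."""
    P, Q, L = count_pq(*alignment)
    d = k2p_gamma_distance(P, Q, alpha)
    return DistanceResult(P=P, Q=Q, alpha=alpha, d=d, L=L)


def pair_distance(seq_a: str, seq_b: str, alpha: float = 1.0,
                  cfg: Optional[LtrConfig] = None) -> DistanceResult:
    return gamma_k2p(align_pair(seq_a, seq_b, cfg), alpha)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# pairing

def pair_substitution_counts(
    copy: LtrSeqs,
    candidates: Sequence[LtrSeqs],
    cfg: Optional[LtrConfig] = None,
) -> LTRPairRecord:
    """Find the most similar copy by 5'-LTR gamma-K2P distance and express
    both divergences as substitution counts on the between-copy alignment
    length: N1 = d(5', closest 5') * L, N2 = d(5', own 3') * L.

    Candidate search is pre-screened by edit distance (``prefilter_k``
    nearest candidates), with the gamma-K2P distance deciding among them;
    exact ties break to the lexicographically smallest copy id.
    """
    cfg = cfg or LtrConfig()
    others = [c for c in candidates if c.copy_id != copy.copy_id and c.ltr5]
    if copy.ltr3 is None or not others:
        return LTRPairRecord(
            copy.copy_id, None, None, None, copy.compartment, None,
            copy.species, "unpaired",
        )
    ranked = sorted(
        others, key=lambda c: (_edit_distance(copy.ltr5, c.ltr5), c.copy_id)
    )[: max(cfg.prefilter_k, 1)]
    best: Optional[tuple[float, str, LtrSeqs, DistanceResult]] = None
    for cand in ranked:
        try:
            res = pair_distance(copy.ltr5, cand.ltr5, cfg.gamma_alpha, cfg)
        except SaturationError:
            continue
        key = (res.d, cand.copy_id)
        if best is None or key < (best[0], best[1]):
            best = (res.d, cand.copy_id, cand, res)
    if best is None:
        return LTRPairRecord(
            copy.copy_id, None, None, None, copy.compartment, None,
            copy.species, "unpaired",
        )
    _, _, closest, between = best
    try:
        within = pair_distance(copy.ltr5, copy.ltr3, cfg.gamma_alpha, cfg)
    except SaturationError:
        return LTRPairRecord(
            copy.copy_id, closest.copy_id, between.substitutions, None,
            copy.compartment, closest.compartment, copy.species, "unpaired",
        )
    # N2 re-expressed on the between-copy aligned length puts the two counts
    # on one scale
    return LTRPairRecord(
        copy_id=copy.copy_id,
        closest_copy_id=closest.copy_id,
        N1=between.d * between.L,
        N2=within.d * between.L,
        compartment=copy.compartment,
        closest_compartment=closest.compartment,
        species=copy.species,
        classification="burst",
    )


def ltr_pair_records(
    copies: Sequence[LtrSeqs],
    cfg: Optional[LtrConfig] = None,
    enforce_min_copies: bool = True,
) -> list[LTRPairRecord]:
    """Pair every copy having both LTRs with its most similar copy.

    Genealogy-stage analyses refuse datasets smaller than the configured
    minimum number of copies (default 100) rather than emitting
    under-powered output.
    """
    cfg = cfg or LtrConfig()
    if enforce_min_copies and len(copies) < cfg.min_copies:
        raise ValueError(
            f"genealogy analysis requires at least {cfg.min_copies} copies, "
            f"got {len(copies)}; lower LtrConfig.min_copies to override"
        )
    return [
        pair_substitution_counts(c, copies, cfg)
        for c in copies
        if c.ltr3 is not None
    ]


# ---------------------------------------------------------------------------
# Poisson null and classification

def build_poisson_null(
    records: Sequence[LTRPairRecord],
    m: int = 10000,
    alpha_level: float = 0.001,
    seed: int = 0,
) -> PoissonNull:
    """Simulate the no-conversion cloud: m points with both coordinates iid
    Poisson(lambda), lambda equal to the observed mean within-copy N2, and
    take the alpha-level tails of D = X2 - X1 as classification thresholds."""
    n2 = [r.N2 for r in records if r.N2 is not None]
    if not n2:
        raise ValueError("no records with defined N2")
    lam = float(np.mean(n2))
    if lam == 0.0:
        return PoissonNull(0.0, m, alpha_level, 0.0, 0.0, seed)
    rng = np.random.default_rng(seed)
    x1 = rng.poisson(lam, size=m)
    x2 = rng.poisson(lam, size=m)
    d = x2 - x1
    upper = float(np.quantile(d, 1.0 - alpha_level))
    lower = float(np.quantile(d, alpha_level))
    return PoissonNull(lam, m, alpha_level, upper, lower, seed)


def classify_pairs(
    records: Iterable[LTRPairRecord], null: PoissonNull
) -> list[LTRPairRecord]:
    """Classify each pair by its distance D = N2 - N1 from the bisector:
    conversion_candidate beyond the upper tail (old copy, homogenized LTRs),
    parent_missing beyond the lower tail (closest relative absent from the
    assembly), burst otherwise.  Records lacking N1 or N2 stay unpaired."""
    out: list[LTRPairRecord] = []
    for rec in records:
        rec = LTRPairRecord(**vars(rec))
        if rec.N1 is None or rec.N2 is None:
            rec.classification = "unpaired"
            out.append(rec)
            continue
        D = rec.N2 - rec.N1
        if D > null.upper_D_threshold:
            rec.classification = "conversion_candidate"
        elif rec.N1 - rec.N2 > -null.lower_D_threshold:
            rec.classification = "parent_missing"
        else:
            rec.classification = "burst"
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# burst clusters

def burst_clusters(
    copies: Sequence[LtrSeqs],
    theta: Optional[float] = None,
    min_size: Optional[int] = None,
    cfg: Optional[LtrConfig] = None,
) -> list[BurstCluster]:
    """Single-linkage clusters of copies at per-site 5'-LTR distance <=
    theta; clusters of at least ``min_size`` members are reported as bursts.

    The per-site distance is the edit distance divided by the longer
    sequence length (for the near-identical copies that define a burst this
    coincides with the substitution proportion).
    """
    cfg = cfg or LtrConfig()
    theta = cfg.cluster_theta if theta is None else theta
    min_size = cfg.cluster_min_size if min_size is None else min_size
    n = len(copies)
    if n == 0:
        return []
    # union-find single linkage on the thresholded distance graph
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            lmax = max(len(copies[i].ltr5), len(copies[j].ltr5))
            if lmax == 0:
                continue
            if _edit_distance(copies[i].ltr5, copies[j].ltr5) / lmax <= theta:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        BurstCluster(
            members=sorted(copies[i].copy_id for i in idxs),
            compartments=[
                copies[i].compartment
                for i in sorted(idxs, key=lambda k: copies[k].copy_id)
            ],
        )
        for idxs in groups.values()
        if len(idxs) >= min_size
    ]
    clusters.sort(key=lambda c: (-c.size, c.members[0]))
    return clusters


# ---------------------------------------------------------------------------
# compartment statistics on pairs

def is_nrr(label: Optional[str]) -> bool:
    return label is not None and label.startswith("NRR")


def nrr_pair_deficit(
    records: Sequence[LTRPairRecord],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float, Optional[float]]:
    """Deficit of closest-copy pairs with both members in the NRR, relative
    to random reassignment of compartment labels to copies.

    Returns (observed both-NRR pairs, permutation expectation, deficit in
    percent); the deficit is undefined (None) when the expectation is zero.
    """
    comp: dict[str, Optional[str]] = {}
    pairs: list[tuple[str, str]] = []
    for rec in records:
        if rec.closest_copy_id is None:
            continue
        comp[rec.copy_id] = rec.compartment
        comp.setdefault(rec.closest_copy_id, rec.closest_compartment)
        pairs.append((rec.copy_id, rec.closest_copy_id))
    ids = sorted(comp)
    labels = np.array([1 if is_nrr(comp[i]) else 0 for i in ids])
    index = {cid: k for k, cid in enumerate(ids)}
    a = np.array([index[p] for p, _ in pairs])
    b = np.array([index[q] for _, q in pairs])
    observed = int(np.sum(labels[a] & labels[b]))
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        counts[i] = np.sum(perm[a] & perm[b])
    expectation = float(counts.mean())
    if expectation == 0.0:
        return observed, expectation, None
    deficit = (expectation - observed) / expectation * 100.0
    return observed, expectation, deficit


def copy_age_comparison(records: Sequence[LTRPairRecord]) -> list[StatResult]:
    """Compare within-copy LTR divergence (N2, a proxy of copy age) between
    compartment classes with a two-way ANOVA (compartment class, species)
    and Tukey-adjusted pairwise compartment comparisons."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = [
        {
            "N2": r.N2,
            "compartment": "NRR" if is_nrr(r.compartment) else (r.compartment or "autosome"),
            "species": r.species or "sp",
        }
        for r in records
        if r.N2 is not None and r.compartment is not None
    ]
    frame = pd.DataFrame(rows)
    if frame.empty or frame["compartment"].nunique() < 2:
        raise ValueError("copy_age_comparison needs >= 2 compartments with records")
    sizes = frame.groupby("compartment").size()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"degenerate compartment group(s): {list(small.index)}")
    formula = "N2 ~ C(compartment)"
    if frame["species"].nunique() > 1:
        formula += " + C(species)"
    model = ols(formula, data=frame).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_stat = float(anova.loc["C(compartment)", "F"])
    p_val = float(anova.loc["C(compartment)", "PR(>F)"])
    results = [
        StatResult("anova_compartment", f_stat, p_val, n=len(frame))
    ]
    tukey = pairwise_tukeyhsd(frame["N2"], frame["compartment"])
    for row in tukey.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], row[2], row[3]
        results.append(
            StatResult(
                f"tukey_{g1}_vs_{g2}", float(meandiff), float(p_adj),
                n=len(frame), adjusted_p=float(p_adj),
            )
        )
    return results


def records_to_frame(records: Iterable[LTRPairRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
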