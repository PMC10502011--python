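"""Ground-truthed synthetic genomes for the TE-accumulation pipeline.

The generator emulates the statistical structure the analysis assumes: two
haploid assemblies (the a1/a2 mating-type genomes of one diploid) sharing
autosomes and pseudo-autosomal regions up to sampled mutations; a
mating-type contig with PARs flanking non-recombining strata of set ages;
planted telomeric motif runs and centromeric repeat arrays; TE copies of
several superfamilies placed at per-compartment target densities; paired
LTRs diverging under a Poisson substitution process; optional gene
conversion between copies; RIP-type C-to-T mutation of TE bodies; and
similarity hit tables with one-violation decoy queries.

Background sequence is AT-rich (GC = 0.25 by default), as expected of the
repeat-dense, RIP-exposed regions the analysis targets; for an i.i.d.
background the neutral normalized RIP index equals -g/(2 - (1-g)/2) for GC
fraction g, so the AT-rich choice keeps the no-RIP baseline near zero.

Every sampled quantity is drawn from a single seeded ``numpy`` generator in
a fixed order, so a fixed seed reproduces the output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Contig, GeneFeature, GenomeAssembly, Interval, TECopy
from .io import HIT_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TEFamilySpec:
    family_id: str
    superfamily: str            # Copia | Ty3 | Helitron | TIR | unclassified
    body_length_bp: int
    ltr_length_bp: Optional[int] = None  # None: no LTR pair


@dataclass
class BurstSpec:
    family_id: str
    burst_age_my: float
    n_copies: int
    #: relative placement weights per compartment class
    compartment_weights: dict = field(
        default_factory=lambda: {"NRR": 0.5, "autosome": 0.4, "PAR": 0.1}
    )


@dataclass
class StratumSpec:
    label: str
    age_my: float
    target_te_fraction: float
    length_bp: int


@dataclass
class SimConfig:
    seed: int = 0
    n_autosomes: int = 3
    autosome_length_bp: int = 400_000
    par_length_bp: int = 150_000
    strata: list[StratumSpec] = field(
        default_factory=lambda: [
            StratumSpec("purple", 2.5, 0.45, 500_000),
            StratumSpec("black", 1.2, 0.35, 400_000),
            StratumSpec("pink", 0.3, 0.12, 200_000),
        ]
    )
    te_families: list[TEFamilySpec] = field(
        default_factory=lambda: [
            TEFamilySpec("copia1", "Copia", 4900, 300),
            TEFamilySpec("ty3_1", "Ty3", 5300, 350),
            TEFamilySpec("hel1", "Helitron", 6000, None),
            TEFamilySpec("tir1", "TIR", 2500, None),
            TEFamilySpec("unk1", "unclassified", 300, None),
        ]
    )
    family_weights: dict = field(
        default_factory=lambda: {
            "copia1": 0.30, "ty3_1": 0.25, "hel1": 0.20,
            "tir1": 0.15, "unk1": 0.10,
        }
    )
    #: substitutions per site per million years on LTR lineages
    mu: float = 0.0025
    #: age of the family root relative to the present (MY); burst ancestors
    #: branch off the root lineage at their burst age
    family_depth_my: float = 5.0
    burst_spec: list[BurstSpec] = field(
        default_factory=lambda: [
            BurstSpec("copia1", 0.2, 150),
            BurstSpec("copia1", 2.0, 100, {"NRR": 0.7, "autosome": 0.3}),
            BurstSpec("ty3_1", 0.5, 120),
        ]
    )
    #: fraction of eligible old copies whose 5'-LTR is overwritten by a donor
    conversion_rate: float = 0.0
    #: per-site RIP conversion probability at target sites, per compartment class
    rip_intensity: dict = field(
        default_factory=lambda: {"NRR": 0.3, "autosome": 0.05, "PAR": 0.05}
    )
    autosome_te_fraction: float = 0.08
    par_te_fraction: float = 0.06
    background_gc: float = 0.25
    fraction_full_length: float = 0.35
    gene_length_bp: int = 1500
    gene_spacing_bp: int = 1000
    haplotype_divergence: float = 1e-4   # per-site a1/a2 mutation rate
    centromere_unit_bp: int = 160
    centromere_units: int = 30
    telomere_repeats: int = 8
    accumulation_params: tuple = (5.0, 50.0, 2.0, 5.0)  # (y0, A, r, noise_sd)

    def validate(self) -> None:
        fractions = (
            [self.autosome_te_fraction, self.par_te_fraction,
             self.conversion_rate, self.fraction_full_length]
            + [s.target_te_fraction for s in self.strata]
            + list(self.rip_intensity.values())
        )
        for f in fractions:
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"rate/fraction {f} outside [0, 1]")
        for s in self.strata:
            if s.target_te_fraction > 0.95:
                raise ConfigError(
                    f"stratum {s.label}: TE fraction {s.target_te_fraction} > 0.95"
                )
        if self.autosome_te_fraction > 0.95 or self.par_te_fraction > 0.95:
            raise ConfigError("TE fraction > 0.95")
        if min(self.autosome_length_bp, self.par_length_bp) <= 0:
            raise ConfigError("lengths must be positive")

    def family(self, family_id: str) -> TEFamilySpec:
        for fam in self.te_families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)


# ---------------------------------------------------------------------------
# sequence primitives

def random_codes(rng: np.random.Generator, n: int, gc: float = 0.25) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def str_to_codes(seq: str) -> np.ndarray:
    codes = _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return codes.copy()


def mutate_codes(codes: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Place ``n_subs`` substitutions uniformly at random (no indels); each
    hit site changes to one of the three other bases."""
    out = codes.copy()
    n = min(n_subs, len(codes))
    if n <= 0:
        return out
    pos = rng.choice(len(codes), size=n, replace=False)
    shift = rng.integers(1, 4, size=n, dtype=np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out


def apply_rip(sequence: str, intensity: float, rng: np.random.Generator) -> str:
    """RIP-type mutation: cytosines in forward TCG context become T, and the
    complementary guanines in forward CGA context become A, each
    independently with probability ``intensity``.  No other position
    changes; the length is preserved."""
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must be in [0, 1]")
    if intensity == 0.0 or len(sequence) < 3:
        return sequence
    seq = list(sequence)
    upper = sequence.upper()
    for i in range(len(upper) - 2):
        tri = upper[i:i + 3]
        if tri == "TCG" and rng.random() < intensity:
            seq[i + 1] = "T"
        elif tri == "CGA" and rng.random() < intensity:
            seq[i + 1] = "A"
    return "".join(seq)


# ---------------------------------------------------------------------------
# LTR history

@dataclass
class SimulatedLtrCopy:
    copy_id: str
    family_id: str
    superfamily: str
    burst_age_my: float
    compartment: str
    ltr5: str
    ltr3: str
    converted: bool = False


def simulate_te_history(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SimulatedLtrCopy], pd.DataFrame]:
    """Simulate LTR-retroelement copies through bursts.

    At insertion a progeny copy's two LTRs equal the burst ancestor's LTR;
    each LTR lineage then accumulates Poisson(mu * age * L) substitutions
    independently.  Conversion (at ``conversion_rate``) overwrites the
    5'-LTR of an old copy (age at least five times the youngest burst age)
    with the 5'-LTR of a young donor copy, leaving the 3'-LTR untouched.

    Returns the copies and a truth table with one row per copy.
    """
    ltr_families = [f for f in config.te_families if f.ltr_length_bp]
    if not ltr_families:
        raise ConfigError("simulate_te_history needs at least one LTR family")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    roots = {
        f.family_id: random_codes(rng, f.ltr_length_bp, config.background_gc)
        for f in ltr_families
    }
    copies: list[SimulatedLtrCopy] = []
    for burst in sorted(
        config.burst_spec, key=lambda b: (b.family_id, b.burst_age_my)
    ):
        fam = config.family(burst.family_id)
        if not fam.ltr_length_bp:
            continue
        L = fam.ltr_length_bp
        expected = config.mu * burst.burst_age_my * L
        if 2 * config.mu * burst.burst_age_my > 0.7:
            import warnings

            warnings.warn(
                f"burst {burst.family_id}@{burst.burst_age_my} MY: expected "
                "LTR divergence near distance-correction saturation",
                stacklevel=2,
            )
        # ancestor branches off the family root lineage at the burst age
        stem = config.mu * max(config.family_depth_my - burst.burst_age_my, 0.0) * L
        ancestor = mutate_codes(roots[burst.family_id], rng.poisson(stem), rng)
        comp_labels = sorted(burst.compartment_weights)
        weights = np.array([burst.compartment_weights[c] for c in comp_labels])
        weights = weights / weights.sum()
        assigned = rng.choice(len(comp_labels), size=burst.n_copies, p=weights)
        for i in range(burst.n_copies):
            ltr5 = mutate_codes(ancestor, rng.poisson(expected), rng)
            ltr3 = mutate_codes(ancestor, rng.poisson(expected), rng)
            copies.append(
                SimulatedLtrCopy(
                    copy_id=f"{burst.family_id}_a{burst.burst_age_my:g}_{i:04d}",
                    family_id=burst.family_id,
                    superfamily=fam.superfamily,
                    burst_age_my=burst.burst_age_my,
                    compartment=comp_labels[assigned[i]],
                    ltr5=codes_to_str(ltr5),
                    ltr3=codes_to_str(ltr3),
                )
            )

    if config.conversion_rate > 0 and copies:
        youngest = min(b.burst_age_my for b in config.burst_spec)
        eligible = [
            i for i, c in enumerate(copies)
            if c.burst_age_my >= 5.0 * youngest
        ]
        donors = [
            i for i, c in enumerate(copies) if c.burst_age_my == youngest
        ] or list(range(len(copies)))
        n_conv = int(round(config.conversion_rate * len(copies)))
        n_conv = min(n_conv, len(eligible))
        chosen = rng.choice(len(eligible), size=n_conv, replace=False)
        for k in chosen:
            idx = eligible[int(k)]
            donor = copies[int(donors[int(rng.integers(len(donors)))])]
            copies[idx].ltr5 = donor.ltr5
            copies[idx].converted = True

    truth = pd.DataFrame(
        [
            {
                "copy_id": c.copy_id,
                "family_id": c.family_id,
                "superfamily": c.superfamily,
                "age_my": c.burst_age_my,
                "compartment": c.compartment,
                "converted": c.converted,
            }
            for c in copies
        ]
    )
    return copies, truth


# ---------------------------------------------------------------------------
# accumulation table

def generate_accumulation_table(
    y0: float, A: float, r: float, ages: Sequence[float],
    noise_sd: float, seed: int,
) -> pd.DataFrame:
    """Stratum (age, TE%) table from the asymptotic accumulation curve
    y(t) = y0 + (A - y0)(1 - exp(-r t)) plus Gaussian noise, truncated to
    [0, 100]."""
    ages = np.asarray(ages, float)
    if (ages < 0).any():
        raise ValueError("ages must be >= 0")
    if not (0 < A <= 100):
        raise ValueError("A must be in (0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    y = y0 + (A - y0) * (1.0 - np.exp(-r * ages))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(ages))
    y = np.clip(y, 0.0, 100.0)
    return pd.DataFrame(
        {
            "event": [f"stratum_{i:02d}" for i in range(len(ages))],
            "age_my": ages,
            "te_percent": y,
        }
    )


# ---------------------------------------------------------------------------
# genome assembly

@dataclass
class TruthTable:
    copies: pd.DataFrame
    compartments: list[tuple[Interval, str]]
    telomeres: list[Interval]
    centromeres: list[Interval]
    strata: pd.DataFrame
    decoys: pd.DataFrame


def _place_genes(gap_start: int, gap_end: int, cfg: SimConfig,
                 counter: list[int], contig: str,
                 stratum: Optional[str]) -> list[GeneFeature]:
    genes = []
    pos = gap_start + 200
    while pos + cfg.gene_length_bp + 200 <= gap_end:
        counter[0] += 1
        genes.append(
            GeneFeature(
                Interval(contig, pos, pos + cfg.gene_length_bp, "+"),
                gene_id=f"gene_{counter[0]:05d}",
                stratum_label=stratum,
            )
        )
        pos += cfg.gene_length_bp + cfg.gene_spacing_bp
    return genes


def _sample_te_instance(cfg: SimConfig, rng: np.random.Generator,
                        compartment_class: str, counter: list[int]):
    """Draw one TE instance: family, length, full/fragment, LTR sequences."""
    fams = sorted(cfg.family_weights)
    w = np.array([cfg.family_weights[f] for f in fams])
    fam_id = fams[int(rng.choice(len(fams), p=w / w.sum()))]
    fam = cfg.family(fam_id)
    counter[0] += 1
    copy_id = f"te_{counter[0]:06d}"
    full = bool(rng.random() < cfg.fraction_full_length)
    ltr5 = ltr3 = None
    age = None
    if fam.ltr_length_bp and full:
        bursts = [b for b in cfg.burst_spec if b.family_id == fam_id]
        if bursts:
            bw = np.array(
                [b.n_copies * b.compartment_weights.get(compartment_class, 0.05)
                 for b in bursts]
            )
            if bw.sum() <= 0:
                bw = np.ones(len(bursts))
            burst = bursts[int(rng.choice(len(bursts), p=bw / bw.sum()))]
            age = burst.burst_age_my
        else:
            age = 0.5
        L = fam.ltr_length_bp
        anc = random_codes(rng, L, cfg.background_gc)
        expected = cfg.mu * age * L
        ltr5 = codes_to_str(mutate_codes(anc, rng.poisson(expected), rng))
        ltr3 = codes_to_str(mutate_codes(anc, rng.poisson(expected), rng))
        body_len = fam.body_length_bp
    elif full:
        body_len = fam.body_length_bp
        age = float(rng.uniform(0.1, 3.0))
    else:
        body_len = int(rng.integers(200, max(fam.body_length_bp // 2, 300)))
        age = float(rng.uniform(0.1, 3.0))
    return copy_id, fam, full, body_len, ltr5, ltr3, age


def _fill_region(
    cfg: SimConfig,
    rng: np.random.Generator,
    contig: str,
    offset: int,
    length: int,
    te_fraction: float,
    compartment_label: str,
    te_counter: list[int],
    gene_counter: list[int],
):
    """Build one compartment region: background sequence with planted TE
    copies up to the target fraction and genes in the intervening gaps.

    Returns (codes, te_rows, genes); coordinates are absolute (offset
    applied)."""
    comp_class = "NRR" if compartment_label.startswith("NRR") else compartment_label
    rip = cfg.rip_intensity.get(comp_class, 0.0)
    pad = 300
    target = te_fraction * length

    instances = []
    total = 0
    while total < target:
        inst = _sample_te_instance(cfg, rng, comp_class, te_counter)
        copy_id, fam, full, body_len, ltr5, ltr3, age = inst
        te_len = body_len + (2 * len(ltr5) if ltr5 else 0)
        if total + te_len > length - 2 * pad:
            break
        instances.append(inst)
        total += te_len

    n_gaps = len(instances) + 1
    free = length - total
    gap_lengths = list(rng.multinomial(free, np.ones(n_gaps) / n_gaps))
    # guarantee TE-free padding at the region ends (telomere/boundary space)
    for edge in (0, -1):
        if gap_lengths[edge] < pad:
            donor = int(np.argmax(gap_lengths))
            gap_lengths[donor] -= pad - gap_lengths[edge]
            gap_lengths[edge] = pad

    pieces: list[np.ndarray] = []
    te_rows = []
    genes: list[GeneFeature] = []
    pos = 0
    stratum = (
        compartment_label.split(":", 1)[1]
        if compartment_label.startswith("NRR:")
        else None
    )
    for k, inst in enumerate(instances):
        glen = int(gap_lengths[k])
        gap = random_codes(rng, glen, cfg.background_gc)
        genes.extend(
            _place_genes(offset + pos, offset + pos + glen, cfg,
                         gene_counter, contig, stratum)
        )
        pieces.append(gap)
        pos += glen

        copy_id, fam, full, body_len, ltr5, ltr3, age = inst
        body = codes_to_str(random_codes(rng, body_len, cfg.background_gc))
        ripped = rip > 0
        if ripped:
            body = apply_rip(body, rip, rng)
        if ltr5 is not None:
            seq = ltr5 + body + ltr3
            l5 = (offset + pos, offset + pos + len(ltr5))
            l3 = (offset + pos + len(ltr5) + body_len,
                  offset + pos + len(ltr5) + body_len + len(ltr3))
        else:
            seq = body
            l5 = l3 = (None, None)
        start = offset + pos
        end = start + len(seq)
        te_rows.append(
            {
                "copy_id": copy_id,
                "family_id": fam.family_id,
                "superfamily": fam.superfamily,
                "contig": contig,
                "start": start,
                "end": end,
                "length": end - start,
                "compartment": compartment_label,
                "full_length": full,
                "age_my": age,
                "ripped": ripped,
                "converted": False,
                "ltr5_start": l5[0], "ltr5_end": l5[1],
                "ltr3_start": l3[0], "ltr3_end": l3[1],
            }
        )
        pieces.append(str_to_codes(seq))
        pos += len(seq)

    glen = length - pos
    gap = random_codes(rng, glen, cfg.background_gc)
    genes.extend(
        _place_genes(offset + pos, offset + pos + glen, cfg,
                     gene_counter, contig, stratum)
    )
    pieces.append(gap)
    codes = np.concatenate(pieces) if pieces else np.empty(0, np.uint8)
    assert len(codes) == length
    return codes, te_rows, genes


def _hit_rows(cfg: SimConfig, rng: np.random.Generator,
              te_rows: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity hit table: each planted copy gets 3-5 qualifying matches;
    decoy queries each violate exactly one retention criterion."""
    rows = []
    for te in te_rows:
        qlen = te["length"]
        n_hits = int(rng.integers(3, 6))
        for _ in range(n_hits):
            ident = float(rng.uniform(82.0, 98.0))
            cov = float(rng.uniform(0.82, 0.98))
            qend = max(int(round(cov * qlen)), 2)
            evalue = 10.0 ** float(rng.uniform(-120.0, -40.0))
            rows.append(
                [te["copy_id"], te["contig"], round(ident, 2), qlen, 0, 0,
                 1, qend, te["start"] + 1, te["end"], evalue,
                 round(2.0 * qlen * ident / 100.0, 1), qlen]
            )

    decoy_rows = []
    decoys = [
        ("decoy_identity", "identity"),
        ("decoy_length", "length"),
        ("decoy_coverage", "coverage"),
        ("decoy_count", "count"),
        ("decoy_evalue", "evalue"),
    ]
    contig = te_rows[0]["contig"] if te_rows else "autosome_1"
    for qid, violation in decoys:
        qlen = 2000
        n = 2 if violation == "count" else 3
        for _ in range(n):
            ident, aln_len, qend, evalue = 90.0, qlen, int(0.9 * qlen), 1e-60
            if violation == "identity":
                ident = 50.0
            elif violation == "length":
                aln_len = 80
            elif violation == "coverage":
                qend = int(0.5 * qlen)
            sstart = int(rng.integers(1, 10_000))
            rows.append([qid, contig, ident, aln_len, 0, 0, 1, qend,
                         sstart, sstart + 1999, evalue, 100.0, qlen])
            # the e-value decoy's three qualifying hits survive the filter;
            # only its extra high-e-value hit (below) must be removed
            decoy_rows.append(
                {"query_id": qid, "violation": violation,
                 "expect_removed": violation != "evalue"}
            )
        if violation == "evalue":
            sstart = int(rng.integers(1, 10_000))
            rows.append([qid, contig, 85.0, qlen, 0, 0, 1, int(0.9 * qlen),
                         sstart, sstart + 1999, 1e-5, 100.0, qlen])
            decoy_rows.append(
                {"query_id": qid, "violation": "evalue_extra_hit",
                 "expect_removed": True}
            )
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS + ["qlen"])
    return frame, pd.DataFrame(decoy_rows)


def assemble_genomes(config: SimConfig):
    """Build the a1/a2 haploid assemblies, the truth table and hit tables.

    Returns (a1, a2, truth, hits) where hits maps haplotype name to a hit
    DataFrame in the 13-column tabular dialect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    te_counter = [0]
    gene_counter = [0]
    contig_codes: dict[str, np.ndarray] = {}
    te_rows: list[dict] = []
    genes: list[GeneFeature] = []
    compartments: list[tuple[Interval, str]] = []
    telomeres: list[Interval] = []
    centromeres: list[Interval] = []
    cen_hits: list[Interval] = []

    tel_run = ("TTAGGG" * cfg.telomere_repeats)
    tel_run_rc = ("CCCTAA" * cfg.telomere_repeats)

    def plant_telomeres(codes: np.ndarray, contig: str) -> None:
        codes[: len(tel_run)] = str_to_codes(tel_run)
        codes[-len(tel_run_rc):] = str_to_codes(tel_run_rc)
        telomeres.append(Interval(contig, 0, 100))
        telomeres.append(Interval(contig, len(codes) - 100, len(codes)))

    # --- autosomes -------------------------------------------------------
    cen_total = cfg.centromere_unit_bp * cfg.centromere_units
    stop_gene = 600
    for a in range(cfg.n_autosomes):
        contig = f"autosome_{a + 1}"
        L = cfg.autosome_length_bp
        half = (L - cen_total - 2 * stop_gene) // 2
        left, te1, g1 = _fill_region(
            cfg, rng, contig, 0, half, cfg.autosome_te_fraction,
            "autosome", te_counter, gene_counter,
        )
        # centromere block: stop genes immediately flanking the repeat array
        unit = random_codes(rng, cfg.centromere_unit_bp, 0.5)
        array = np.tile(unit, cfg.centromere_units)
        cen_start = half + stop_gene
        cen_end = cen_start + cen_total
        gene_counter[0] += 1
        g_left = GeneFeature(
            Interval(contig, cen_start - stop_gene, cen_start, "+"),
            f"gene_{gene_counter[0]:05d}",
        )
        gene_counter[0] += 1
        g_right = GeneFeature(
            Interval(contig, cen_end, cen_end + stop_gene, "+"),
            f"gene_{gene_counter[0]:05d}",
        )
        right_start = cen_end + stop_gene
        right, te2, g2 = _fill_region(
            cfg, rng, contig, right_start, L - right_start,
            cfg.autosome_te_fraction, "autosome", te_counter, gene_counter,
        )
        codes = np.concatenate(
            [left, random_codes(rng, stop_gene, cfg.background_gc), array,
             random_codes(rng, stop_gene, cfg.background_gc), right]
        )
        # stop genes overwrite background only in annotation, not sequence
        plant_telomeres(codes, contig)
        contig_codes[contig] = codes
        te_rows += te1 + te2
        genes += g1 + [g_left, g_right] + g2
        centromeres.append(Interval(contig, cen_start, cen_end))
        for u in range(cfg.centromere_units):
            s = cen_start + u * cfg.centromere_unit_bp
            cen_hits.append(Interval(contig, s, s + cfg.centromere_unit_bp))

    # --- mating-type contig ---------------------------------------------
    contig = "mating_type"
    regions: list[tuple[str, int, float]] = [
        ("PAR", cfg.par_length_bp, cfg.par_te_fraction)
    ]
    for s in cfg.strata:
        regions.append((f"NRR:{s.label}", s.length_bp, s.target_te_fraction))
    regions.append(("PAR", cfg.par_length_bp, cfg.par_te_fraction))
    pieces = []
    offset = 0
    strata_rows = []
    for label, length, frac in regions:
        codes, trs, gs = _fill_region(
            cfg, rng, contig, offset, length, frac, label,
            te_counter, gene_counter,
        )
        pieces.append(codes)
        te_rows += trs
        genes += gs
        compartments.append((Interval(contig, offset, offset + length), label))
        if label.startswith("NRR:"):
            spec = next(s for s in cfg.strata if f"NRR:{s.label}" == label)
            placed = sum(t["length"] for t in trs)
            strata_rows.append(
                {
                    "stratum": spec.label,
                    "age_my": spec.age_my,
                    "length_bp": length,
                    "target_te_fraction": spec.target_te_fraction,
                    "placed_te_fraction": placed / length,
                }
            )
        offset += length
    codes = np.concatenate(pieces)
    plant_telomeres(codes, contig)
    contig_codes[contig] = codes

    for a in range(cfg.n_autosomes):
        compartments.append(
            (Interval(f"autosome_{a + 1}", 0, cfg.autosome_length_bp), "autosome")
        )

    # --- haplotypes ------------------------------------------------------
    def build_assembly(divergence: float) -> GenomeAssembly:
        contigs = {}
        for cid, base_codes in contig_codes.items():
            c = base_codes
            if divergence > 0:
                n_mut = rng.poisson(divergence * len(c))
                c = mutate_codes(c, n_mut, rng)
            contigs[cid] = Contig(cid, codes_to_str(c))
        return GenomeAssembly(
            contigs=contigs,
            genes=[GeneFeature(g.interval, g.gene_id, g.stratum_label) for g in genes],
            te_copies=[_row_to_copy(t) for t in te_rows],
            bed_layers={"centromere_hits": list(cen_hits)},
        )

    a1 = build_assembly(0.0)
    a2 = build_assembly(cfg.haplotype_divergence)

    hits1, decoys = _hit_rows(cfg, rng, te_rows)
    hits2, _ = _hit_rows(cfg, rng, te_rows)
    truth = TruthTable(
        copies=pd.DataFrame(te_rows),
        compartments=compartments,
        telomeres=telomeres,
        centromeres=centromeres,
        strata=pd.DataFrame(strata_rows),
        decoys=decoys,
    )
    return a1, a2, truth, {"a1": hits1, "a2": hits2}


def _row_to_copy(row: dict) -> TECopy:
    ltr5 = ltr3 = None
    if row["ltr5_start"] is not None:
        ltr5 = Interval(row["contig"], row["ltr5_start"], row["ltr5_end"])
        ltr3 = Interval(row["contig"], row["ltr3_start"], row["ltr3_end"])
    return TECopy(
        copy_id=row["copy_id"],
        interval=Interval(row["contig"], row["start"], row["end"], "+"),
        categories=[row["superfamily"]],
        family_id=row["family_id"],
        ltr5=ltr5,
        ltr3=ltr3,
        compartment=row["compartment"],
    )
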