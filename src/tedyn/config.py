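"""Pipeline configuration: one dataclass namespace per analysis stage.

Every threshold of the analysis is a config key; defaults follow the values
used throughout the package documentation.  A TOML file with matching
section names overrides individual keys.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from typing import Optional, Union


@dataclass
class FilterConfig:
    """Hit-retention thresholds for TE-candidate filtering."""

    min_matches: int = 3            # repeat criterion: >= 3 same-species matches
    min_identity: float = 0.8
    min_length_bp: int = 100        # strict: length > 100 bp
    min_coverage: float = 0.8
    #: secondary-retention e-value threshold; either a number or "q25" for
    #: the 25th percentile of the e-values of qualifying queries' hits
    evalue_threshold: Union[float, str] = "q25"
    annotation_evalue: float = 1e-10
    rrna_mito_evalue: float = 1e-10


@dataclass
class RipConfig:
    window_bp: int = 1000
    #: tetranucleotide subtracted from the RIP-target count because it holds
    #: both a forward TCG and a reverse-strand CGA site
    overlap_motif: str = "TCGA"
    smooth_window_bp: int = 10000
    smooth_step_bp: int = 10000


@dataclass
class FeatureConfig:
    telomere_motif: str = "TTAGGG"
    telomere_terminal_bp: int = 100
    telomere_min_count: int = 5
    subtelomere_bp: int = 20000
    centromere_min_contig_bp: int = 20000
    centromere_merge_gap_bp: int = 1000
    centromere_step_bp: int = 1000
    centromere_max_gene_density: float = 0.25
    margin_window_bp: int = 100000
    margin_min_windows: int = 30
    margin_centromere_buffer_bp: int = 100000


@dataclass
class LtrConfig:
    gamma_alpha: float = 1.0        # gamma shape of the K2P rate correction
    alpha_level: float = 0.001      # tail level of the Poisson-null cloud test
    null_points: int = 10000
    cluster_theta: float = 0.01     # single-linkage per-site distance cutoff
    cluster_min_size: int = 5
    min_copies: int = 100           # refuse genealogy analyses below this
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -4
    gap_extend: int = -1
    prefilter_k: int = 5            # closest-copy candidates kept by edit distance


@dataclass
class DynamicsConfig:
    min_block_bp: int = 80000
    min_block_genes: int = 2
    time_zero_age_my: float = 3e-8
    exclude_strata: list[str] = field(default_factory=list)
    spline_df: int = 5
    negexp_r_starts: tuple = (0.1, 0.5, 1.0, 2.0, 5.0)


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    rip: RipConfig = field(default_factory=RipConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ltr: LtrConfig = field(default_factory=LtrConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a TOML config; keys not present keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for section_name, section in data.items():
        if not hasattr(cfg, section_name):
            raise KeyError(f"unknown config section {section_name!r}")
        target = getattr(cfg, section_name)
        valid = {f.name for f in dataclasses.fields(target)}
        for key, value in section.items():
            if key not in valid:
                raise KeyError(f"unknown config key {section_name}.{key}")
            setattr(target, key, value)
    return cfg
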