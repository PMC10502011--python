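"""Evolutionary-strata aggregation and TE-accumulation dynamics.

Each independent recombination-suppression event contributes one (age,
TE%) point: TE content is averaged over the two mating-type haplotypes of a
species and then over the species sharing the event.  The accumulation of
TEs with time since recombination suppression is modelled by competing
regressions — linear, logarithmic, penalized spline, and the asymptotic
(negative-exponential) model

    y(t) = y0 + (A - y0) (1 - exp(-r t))

compared by AIC under a Gaussian likelihood (k = number of mean parameters
plus one for the residual variance).  The fitted curve is summarized by its
asymptote A and the time to 95% of the plateau, t95 = ln(20)/r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

from .config import DynamicsConfig
from .core import GeneFeature, Interval, StatResult

_RSS_FLOOR = 1e-12  # keeps the Gaussian AIC finite on noiseless data


@dataclass
class StratumRecord:
    stratum_id: str
    age_my: float
    te_percent: float
    age_lo: Optional[float] = None
    age_hi: Optional[float] = None
    ancestral_size_bp: Optional[float] = None
    ds: Optional[float] = None
    species_list: list[str] = field(default_factory=list)


@dataclass
class AccumulationFit:
    model: str
    params: dict
    aic: float
    rss: float
    n: int
    k: float
    fitted: np.ndarray
    converged: bool = True
    message: str = ""


@dataclass
class PhyloSignalResult:
    lambda_hat: float
    p_lambda0: float
    p_lambda1: float
    slope: float
    intercept: float
    log_likelihood: float
    warning: Optional[str] = None


# ---------------------------------------------------------------------------
# stratum blocks

def assign_stratum_blocks(
    genes: Sequence[GeneFeature],
    region_by_contig: dict[str, tuple[int, int]],
    cfg: Optional[DynamicsConfig] = None,
) -> tuple[list[tuple[Interval, str]], dict]:
    """Partition non-recombining regions into stratum blocks.

    Maximal runs of consecutive same-stratum genes become candidate blocks;
    the boundary between two adjacent runs is the midpoint between the inner
    edges of their flanking genes, and the first/last blocks extend to the
    region bounds.  Blocks shorter than 80 kb or holding fewer than two
    genes are discarded.  Returns the retained blocks and a coverage report
    (retained bases as a percentage of the region bases).
    """
    cfg = cfg or DynamicsConfig()
    unlabeled = [g.gene_id for g in genes if g.stratum_label is None]
    if unlabeled:
        raise ValueError(f"genes without stratum label: {unlabeled}")

    blocks: list[tuple[Interval, str]] = []
    discarded: list[tuple[Interval, str, str]] = []
    for contig_id, (reg_start, reg_end) in sorted(region_by_contig.items()):
        contig_genes = sorted(
            (g for g in genes if g.interval.contig_id == contig_id),
            key=lambda g: g.interval.start,
        )
        if not contig_genes:
            continue
        runs: list[list[GeneFeature]] = [[contig_genes[0]]]
        for g in contig_genes[1:]:
            if g.stratum_label == runs[-1][-1].stratum_label:
                runs[-1].append(g)
            else:
                runs.append([g])
        bounds = [reg_start]
        for prev, nxt in zip(runs[:-1], runs[1:]):
            bounds.append((prev[-1].interval.end + nxt[0].interval.start) // 2)
        bounds.append(reg_end)
        for run, s, e in zip(runs, bounds[:-1], bounds[1:]):
            iv = Interval(contig_id, s, e)
            label = run[0].stratum_label
            if len(run) < cfg.min_block_genes:
                discarded.append((iv, label, "fewer than 2 genes"))
            elif iv.length < cfg.min_block_bp:
                discarded.append((iv, label, f"block < {cfg.min_block_bp} bp"))
            else:
                blocks.append((iv, label))

    total = sum(e - s for s, e in region_by_contig.values())
    retained = sum(iv.length for iv, _ in blocks)
    report = {
        "total_bases": total,
        "retained_bases": retained,
        "retained_percent": 100.0 * retained / total if total else None,
        "discarded": discarded,
    }
    return blocks, report


# ---------------------------------------------------------------------------
# aggregation across haplotypes, species and events

def aggregate_event_te_content(
    per_haplotype: pd.DataFrame,
    event_of_stratum: dict[str, str],
    time_zero_te_percent: Optional[float] = None,
    cfg: Optional[DynamicsConfig] = None,
) -> pd.DataFrame:
    """Mean TE percent per independent recombination-suppression event.

    ``per_haplotype`` needs columns stratum_id, species, haplotype,
    te_percent and optionally age_MY / ancestral_size_bp.  Each stratum must
    be present in both haplotypes of each species.  When
    ``time_zero_te_percent`` is given (autosomal TE content of an outgroup
    with recombining mating-type chromosomes), a time-zero record at
    3e-8 MY is appended.
    """
    cfg = cfg or DynamicsConfig()
    df = per_haplotype.copy()
    missing = set(df["stratum_id"]) - set(event_of_stratum)
    if missing:
        raise KeyError(f"strata without an event assignment: {sorted(missing)}")
    df = df[~df["stratum_id"].isin(cfg.exclude_strata)]

    counts = df.groupby(["species", "stratum_id"])["haplotype"].nunique()
    incomplete = counts[counts < 2]
    if not incomplete.empty:
        raise ValueError(
            f"strata missing in one haplotype: {list(incomplete.index)}"
        )
    aggregates = {"te_percent": ("te_percent", "mean")}
    if "age_MY" in df:
        aggregates["age_my"] = ("age_MY", "mean")
    if "ancestral_size_bp" in df:
        aggregates["ancestral_size_bp"] = ("ancestral_size_bp", "mean")
    per_species = df.groupby(["species", "stratum_id"], as_index=False).agg(**aggregates)
    per_species["event"] = per_species["stratum_id"].map(event_of_stratum)
    rows = []
    for event, grp in per_species.groupby("event"):
        rows.append(
            {
                "event": event,
                "stratum_ids": ",".join(sorted(grp["stratum_id"].unique())),
                "species_list": ",".join(sorted(grp["species"].unique())),
                "n_species": grp["species"].nunique(),
                "te_percent": grp["te_percent"].mean(),
                "age_my": grp["age_my"].mean() if "age_MY" in df else None,
                "ancestral_size_bp": (
                    grp["ancestral_size_bp"].mean()
                    if "ancestral_size_bp" in df
                    else None
                ),
            }
        )
    columns = ["event", "stratum_ids", "species_list", "n_species",
               "te_percent", "age_my", "ancestral_size_bp"]
    out = pd.DataFrame(rows, columns=columns).sort_values("event", ignore_index=True)
    if time_zero_te_percent is not None:
        zero = {
            "event": "time_zero",
            "stratum_ids": "autosomes",
            "species_list": "outgroup",
            "n_species": 1,
            "te_percent": time_zero_te_percent,
            "age_my": cfg.time_zero_age_my,
            "ancestral_size_bp": None,
        }
        out = pd.concat([out, pd.DataFrame([zero])], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# accumulation models

def negexp(t: np.ndarray, y0: float, A: float, r: float) -> np.ndarray:
    return y0 + (A - y0) * (1.0 - np.exp(-r * t))


def _gaussian_aic(rss: float, n: int, k: float) -> float:
    sigma2 = max(rss, _RSS_FLOOR) / n
    return n * math.log(2.0 * math.pi * sigma2) + n + 2.0 * k


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return beta, fitted, rss


def _cr_basis(t: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic regression spline: natural cubic spline parameterized by its
    values at ``df`` knots (placed at quantiles of the data), with the
    integrated-squared-second-derivative wiggliness penalty.

    Returns the design matrix X (function values at ``t``) and the penalty
    matrix S; the penalty null space is the constant and linear functions.
    """
    knots = np.quantile(np.unique(t), np.linspace(0, 1, df))
    if len(np.unique(knots)) < df:
        raise np.linalg.LinAlgError("degenerate knot placement")
    h = np.diff(knots)
    k = df
    # second derivatives at interior knots: delta = F @ beta
    D = np.zeros((k - 2, k))
    Bmat = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        Bmat[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            Bmat[i, i + 1] = h[i + 1] / 6.0
            Bmat[i + 1, i] = h[i + 1] / 6.0
    F_int = np.linalg.solve(Bmat, D)
    F = np.vstack([np.zeros(k), F_int, np.zeros(k)])  # natural: delta_1 = delta_k = 0
    S = D.T @ np.linalg.solve(Bmat, D)

    X = np.zeros((len(t), k))
    spans = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, k - 2)
    for row, (x, j) in enumerate(zip(t, spans)):
        hj = h[j]
        am = (knots[j + 1] - x) / hj
        ap = (x - knots[j]) / hj
        cm = ((knots[j + 1] - x) ** 3 / hj - hj * (knots[j + 1] - x)) / 6.0
        cp = ((x - knots[j]) ** 3 / hj - hj * (x - knots[j])) / 6.0
        X[row] = am * np.eye(k)[j] + ap * np.eye(k)[j + 1] + cm * F[j] + cp * F[j + 1]
    return X, S


def _penalized_spline_fit(
    t: np.ndarray, y: np.ndarray, df: int, extra: Optional[np.ndarray] = None
) -> tuple[np.ndarray, float, float, float]:
    """Penalized cubic regression spline; the penalty weight is chosen by
    generalized cross-validation.  Returns (fitted, rss, edf, lambda)."""
    B, P = _cr_basis(t, df)
    if extra is not None:
        B = np.hstack([B, extra])
        pad = extra.shape[1]
        P = np.pad(P, ((0, pad), (0, pad)))
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(y)
    best = None
    for lam in np.logspace(-6, 6, 40):
        try:
            coef = np.linalg.solve(BtB + lam * P, Bty)
            hat_core = np.linalg.solve(BtB + lam * P, BtB)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(hat_core))
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        denom = max(n - edf, 1e-6)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, fitted, rss, edf, lam)
    if best is None:
        raise np.linalg.LinAlgError("spline fit failed for all penalties")
    _, fitted, rss, edf, lam = best
    return fitted, rss, edf, lam


def _fit_negexp(
    t: np.ndarray,
    y: np.ndarray,
    extra: Optional[np.ndarray],
    y0_fixed: Optional[float],
    r_starts: Sequence[float],
) -> tuple[Optional[dict], Optional[np.ndarray], float, int]:
    """Multi-start nonlinear least squares; returns (params, fitted, rss,
    n_free_params) or (None, None, inf, 0) when no start converges."""
    n_extra = 0 if extra is None else extra.shape[1]

    def unpack(theta):
        i = 0
        if y0_fixed is None:
            y0 = theta[0]
            i = 1
        else:
            y0 = y0_fixed
        A, r = theta[i], theta[i + 1]
        betas = theta[i + 2:]
        return y0, A, r, betas

    def resid(theta):
        y0, A, r, betas = unpack(theta)
        mu = negexp(t, y0, A, r)
        if n_extra:
            mu = mu + extra @ betas
        return y - mu

    best: Optional[tuple[float, np.ndarray]] = None
    a_starts = [float(np.max(y)), 1.2 * float(np.max(y))]
    for r0 in r_starts:
        for a0 in a_starts:
            theta0 = []
            if y0_fixed is None:
                theta0.append(float(np.min(y)))
            theta0 += [a0, r0] + [0.0] * n_extra
            try:
                sol = optimize.least_squares(resid, np.array(theta0), method="lm",
                                             max_nfev=5000)
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        return None, None, math.inf, 0
    rss, theta = best
    y0, A, r, betas = unpack(theta)
    fitted = y - resid(theta)
    params = {"y0": float(y0), "A": float(A), "r": float(r)}
    for j, b in enumerate(np.atleast_1d(betas)):
        params[f"beta_cov{j}"] = float(b)
    n_free = len(theta)
    return params, fitted, rss, n_free


def fit_accumulation_models(
    records: pd.DataFrame,
    with_covariable: bool = False,
    y0_fixed: Optional[float] = None,
    cfg: Optional[DynamicsConfig] = None,
) -> tuple[list[AccumulationFit], AccumulationFit]:
    """Fit and compare the candidate accumulation models by AIC.

    ``records`` needs columns age_my and te_percent (and ancestral_size_bp
    when ``with_covariable``).  Models: linear in t, linear in ln t,
    penalized cubic spline in t, and the negative-exponential asymptotic
    model.  Returns all fits and the AIC-best one.
    """
    cfg = cfg or DynamicsConfig()
    df = records.dropna(subset=["age_my", "te_percent"]).sort_values("age_my")
    t = df["age_my"].to_numpy(float)
    y = df["te_percent"].to_numpy(float)
    n = len(df)
    if n < 6:
        raise ValueError(f"need >= 6 records to compare models, got {n}")
    if (t <= 0).any():
        raise ValueError("ages must be > 0 (use the small time-zero age)")
    extra = None
    if with_covariable:
        cov = df["ancestral_size_bp"].to_numpy(float)
        cov = np.where(np.isnan(cov), np.nanmean(cov), cov)
        extra = ((cov - cov.mean()) / max(cov.std(), 1e-9)).reshape(-1, 1)

    fits: list[AccumulationFit] = []

    def _add_ols(name: str, X0: np.ndarray, param_names: list[str]) -> None:
        X = X0 if extra is None else np.hstack([X0, extra])
        beta, fitted, rss = _ols_fit(X, y)
        k = X.shape[1] + 1
        fits.append(
            AccumulationFit(
                model=name,
                params=dict(zip(param_names + [f"beta_cov{j}" for j in
                                               range(0 if extra is None else extra.shape[1])],
                                beta.tolist())),
                aic=_gaussian_aic(rss, n, k), rss=rss, n=n, k=k, fitted=fitted,
            )
        )

    _add_ols("linear", np.column_stack([np.ones(n), t]), ["intercept", "slope"])
    _add_ols("log", np.column_stack([np.ones(n), np.log(t)]), ["intercept", "slope"])

    try:
        fitted, rss, edf, lam = _penalized_spline_fit(t, y, cfg.spline_df, extra)
        k = edf + 1.0
        fits.append(
            AccumulationFit("spline", {"edf": edf, "lambda": lam},
                            _gaussian_aic(rss, n, k), rss, n, k, fitted)
        )
    except np.linalg.LinAlgError as exc:
        fits.append(
            AccumulationFit("spline", {}, math.inf, math.inf, n, 0.0,
                            np.full(n, np.nan), converged=False, message=str(exc))
        )

    params, fitted, rss, n_free = _fit_negexp(
        t, y, extra, y0_fixed, cfg.negexp_r_starts
    )
    if params is None:
        fits.append(
            AccumulationFit("negexp", {}, math.inf, math.inf, n, 0.0,
                            np.full(n, np.nan), converged=False,
                            message="no start converged")
        )
    else:
        k = n_free + 1
        fits.append(
            AccumulationFit("negexp", params, _gaussian_aic(rss, n, k),
                            rss, n, k, fitted)
        )

    best = min((f for f in fits if f.converged), key=lambda f: f.aic)
    return fits, best


def plateau_summary(fit: AccumulationFit) -> dict:
    """Asymptote and time to 95% of the plateau for a converged
    negative-exponential fit; r <= 0 carries no plateau."""
    if fit.model != "negexp" or not fit.converged:
        raise ValueError("plateau_summary needs a converged negexp fit")
    r = fit.params["r"]
    if r <= 0:
        return {"A": fit.params["A"], "t95_my": None, "plateau": False}
    return {"A": fit.params["A"], "t95_my": math.log(20.0) / r, "plateau": True}


# ---------------------------------------------------------------------------
# phylogenetic signal (Pagel's lambda GLS)

def _vcv_from_tree(tree, taxon_labels: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix (shared root-path lengths) for the
    named tips of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [lab for lab in taxon_labels if lab not in taxa]
    if missing:
        raise KeyError(f"tree is missing tips: {missing}")
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    k = len(taxon_labels)
    V = np.zeros((k, k))
    for i, a in enumerate(taxon_labels):
        for j, b in enumerate(taxon_labels):
            if i == j:
                V[i, j] = depths[a]
            else:
                dij = pdm.patristic_distance(taxa[a], taxa[b])
                V[i, j] = (depths[a] + depths[b] - dij) / 2.0
    return V


def _gls_loglik(lam: float, V: np.ndarray, X: np.ndarray, y: np.ndarray):
    C = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    n = len(y)
    try:
        Ci = np.linalg.inv(C)
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return -math.inf, None
    except np.linalg.LinAlgError:
        return -math.inf, None
    XtCi = X.T @ Ci
    beta = np.linalg.solve(XtCi @ X, XtCi @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ Ci @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-12
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, beta


def phylo_signal_test(
    records: pd.DataFrame, tree, label_col: str = "event",
    x_col: str = "age_my", y_col: str = "te_percent",
) -> PhyloSignalResult:
    """Pagel's-lambda GLS regression of TE content on stratum age.

    The residual covariance is lambda-scaled Brownian motion on the supplied
    ultrametric tree (off-diagonals multiplied by lambda, diagonal kept);
    lambda is estimated by maximum likelihood on [0, 1] and compared to the
    lambda = 0 and lambda = 1 boundaries by likelihood-ratio tests.
    """
    labels = records[label_col].tolist()
    V = _vcv_from_tree(tree, labels)
    y = records[y_col].to_numpy(float)
    X = np.column_stack([np.ones(len(y)), records[x_col].to_numpy(float)])

    warning = None
    off = V[~np.eye(len(V), dtype=bool)]
    if np.allclose(off, 0.0):
        warning = "star tree: lambda unidentifiable"

    def nll(lam: float) -> float:
        ll, _ = _gls_loglik(lam, V, X, y)
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded")
    lam_hat = float(res.x)
    ll_hat, beta = _gls_loglik(lam_hat, V, X, y)
    ll0, _ = _gls_loglik(0.0, V, X, y)
    ll1, _ = _gls_loglik(1.0, V, X, y)
    for ll_b in (ll0, ll1):
        if ll_b > ll_hat:  # boundary beats interior optimum
            lam_hat = 0.0 if ll_b == ll0 else 1.0
            ll_hat, beta = _gls_loglik(lam_hat, V, X, y)
    p0 = float(stats.chi2.sf(max(2.0 * (ll_hat - ll0), 0.0), 1))
    p1 = float(stats.chi2.sf(max(2.0 * (ll_hat - ll1), 0.0), 1))
    return PhyloSignalResult(
        lambda_hat=lam_hat, p_lambda0=p0, p_lambda1=p1,
        slope=float(beta[1]), intercept=float(beta[0]),
        log_likelihood=ll_hat, warning=warning,
    )


# ---------------------------------------------------------------------------
# local regression of intact fractions

def _loess_fit(x: np.ndarray, y: np.ndarray, span: float) -> tuple[np.ndarray, float]:
    """Local linear regression with tricube weights; returns fitted values
    at the observed x and the effective degrees of freedom (trace of the
    smoother matrix)."""
    n = len(x)
    q = max(int(math.ceil(span * n)), 3)
    L = np.zeros((n, n))
    for i in range(n):
        dist = np.abs(x - x[i])
        radius = np.sort(dist)[min(q, n) - 1]
        if radius == 0:
            radius = max(dist.max(), 1e-12)
        w = np.clip(1 - (dist / radius) ** 3, 0, None) ** 3
        active = w > 0
        Xl = np.column_stack([np.ones(active.sum()), x[active] - x[i]])
        W = np.diag(w[active])
        try:
            H = np.linalg.solve(Xl.T @ W @ Xl, Xl.T @ W)
        except np.linalg.LinAlgError:
            H = np.linalg.pinv(Xl.T @ W @ Xl) @ (Xl.T @ W)
        row = np.zeros(n)
        row[active] = H[0]
        L[i] = row
    fitted = L @ y
    edf = float(np.trace(L))
    return fitted, edf


def intact_fraction_trend(
    ages: Sequence[float],
    fractions: Sequence[float],
    spans: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> dict:
    """Local linear regression of intact-copy fractions on stratum age with
    the span chosen by corrected AIC over a grid; returns the chosen span,
    fitted values at the observed ages, and the AICc per span."""
    x = np.asarray(ages, float)
    y = np.asarray(fractions, float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 points for the local regression, got {n}")
    order = np.argsort(x)
    x, y = x[order], y[order]
    table = []
    best = None
    for span in spans:
        fitted, edf = _loess_fit(x, y, span)
        rss = float(np.sum((y - fitted) ** 2))
        denom = n - edf - 2.0
        if denom <= 0:
            continue
        sigma2 = max(rss, _RSS_FLOOR) / n
        aicc = n * math.log(sigma2) + 2.0 * (edf + 1.0) * n / denom
        table.append({"span": span, "aicc": aicc, "rss": rss, "edf": edf})
        if best is None or aicc < best["aicc"]:
            best = {"span": span, "aicc": aicc, "rss": rss,
                    "fitted": fitted, "edf": edf}
    if best is None:
        raise ValueError("no span had enough support for the local regression")
    return {
        "span": best["span"],
        "ages": x,
        "fitted": best["fitted"],
        "edf": best["edf"],
        "rss": best["rss"],
        "grid": pd.DataFrame(table),
    }


# ---------------------------------------------------------------------------
# standard group tests

def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Paired two-sided Wilcoxon signed-rank test, zero differences dropped
    (exact null for n < 50).  All-zero differences return p = 1, flagged."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return StatResult("wilcoxon_paired", 0.0, 1.0, n=len(a),
                          note="all paired differences zero")
    method = "exact" if len(nonzero) < 50 else "approx"
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
    return StatResult("wilcoxon_paired", float(stat), float(p), n=len(nonzero))


def anova_tukey(
    frame: pd.DataFrame, value: str, group: str,
    block: Optional[str] = None, interaction: Optional[str] = None,
) -> list[StatResult]:
    """ANOVA on ``value`` by ``group`` (optional blocking factor and
    interaction term) with Tukey-adjusted pairwise group comparisons."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = frame.dropna(subset=[value]).rename(
        columns={value: "_y", group: "_g"}
    )
    variances = df.groupby("_g")["_y"].var()
    if (variances.fillna(0.0) == 0.0).all() and df["_g"].nunique() > 1 and len(df) > df["_g"].nunique():
        bad = variances.index.tolist()
        raise ValueError(f"degenerate (zero-variance) groups: {bad}")
    formula = "_y ~ C(_g)"
    if block is not None:
        df = df.rename(columns={block: "_b"})
        formula += " + C(_b)"
        if interaction == block:
            formula += " + C(_g):C(_b)"
    elif interaction is not None:
        df = df.rename(columns={interaction: "_i"})
        formula += " + C(_i) + C(_g):C(_i)"
    model = ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = [
        StatResult(
            "anova_" + str(idx), float(row["F"]), float(row["PR(>F)"]),
            n=len(df),
        )
        for idx, row in anova.iterrows()
        if not math.isnan(row["F"])
    ]
    tukey = pairwise_tukeyhsd(df["_y"], df["_g"])
    for row in tukey.summary().data[1:]:
        out.append(
            StatResult(
                f"tukey_{row[0]}_vs_{row[1]}", float(row[2]), float(row[3]),
                n=len(df), adjusted_p=float(row[3]),
            )
        )
    return out


def pearson_test(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Pearson correlation test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) variable in correlation test")
    r, p = stats.pearsonr(x, y)
    return StatResult("pearson", float(r), float(p), n=len(x))


def basic_group_tests(
    paired: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    anova: Optional[tuple[pd.DataFrame, str, str]] = None,
    correlations: Optional[dict[str, tuple[Sequence[float], Sequence[float]]]] = None,
) -> list[StatResult]:
    """Convenience dispatcher bundling the standard tests of the pipeline."""
    results: list[StatResult] = []
    if paired is not None:
        results.append(wilcoxon_paired(*paired))
    if anova is not None:
        results.extend(anova_tukey(*anova))
    for name, (x, y) in (correlations or {}).items():
        res = pearson_test(x, y)
        res.test_name = f"pearson_{name}"
        results.append(res)
    return results
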