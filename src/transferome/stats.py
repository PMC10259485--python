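"""Transfer inference on RPM matrices.

Implements the study's statistics: background-corrected foreign-read
proportions, one-tailed unpaired t detection with the two-stage
Benjamini-Krieger-Yekutieli (BKY) FDR, the per-gene percentage-transfer
statistic with its expression filters, spot-count transfer percentages,
expression-dependence regression with a pointwise confidence band,
log-scale Gaussian distribution fits, hypergeometric gene-set overlap, and
post-hoc differential-expression thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import TransferomeError

FILTER_FLAGS = ("low_single_expression", "low_coculture_signal", "low_fc")


# ---------------------------------------------------------------------------
# Background-corrected foreign-read proportions

@dataclass
class ProportionCorrection:
    """Foreign-read percentages after subtracting the library background.

    The single-culture background (index hopping during library prep /
    sequencing) is subtracted from the Mix and Co-culture means; the ratio
    Co-culture/Mix of the corrected values measures how much foreign signal
    exceeds what residual-cell contamination alone explains.
    """

    pct_mix: list[float]
    pct_coculture: list[float]
    pct_single: list[float]
    corrected_mix: float
    corrected_coculture: float
    ratio: float  # NaN when undefined
    note: str | None = None


def corrected_foreign_proportion(
    pct_mix, pct_coculture, pct_single
) -> ProportionCorrection:
    """Subtract the single-culture background from Mix and Co-culture means.

    Inputs are replicate percentages of foreign reads over total reads.
    The ratio is undefined (NaN, with a diagnostic note) when the corrected
    Mix value is <= 0.
    """
    groups = [list(map(float, g)) for g in (pct_mix, pct_coculture, pct_single)]
    if any(len(g) < 1 for g in groups):
        raise TransferomeError("each group needs at least one replicate")
    mix, co, single = (float(np.mean(g)) for g in groups)
    corrected_mix = mix - single
    corrected_co = co - single
    if corrected_mix <= 0:
        return ProportionCorrection(
            groups[0], groups[1], groups[2], corrected_mix, corrected_co,
            float("nan"),
            note="ratio undefined: corrected Mix proportion is <= 0 "
            "(background exceeds or equals signal)",
        )
    return ProportionCorrection(
        groups[0], groups[1], groups[2], corrected_mix, corrected_co,
        corrected_co / corrected_mix,
    )


# ---------------------------------------------------------------------------
# One-tailed unpaired t-test (Student, equal variance)

def one_tailed_unpaired_t(co_values, mix_values) -> tuple[float, float]:
    """Student's equal-variance t, alternative: co-culture mean > mix mean.

    Convention for degenerate inputs: when both groups have zero variance
    the t statistic is undefined (the pooled standard error is 0) and no
    significance can be claimed from it, so p = 1 regardless of the means;
    t is reported as 0. Exact within-group ties are a small-count artifact
    rather than evidence, and this convention keeps the detector's false
    discovery rate controlled on count data.
    """
    co = np.asarray(co_values, dtype=float)
    mix = np.asarray(mix_values, dtype=float)
    if co.size < 2 or mix.size < 2:
        raise TransferomeError("need >= 2 values per group")
    if co.std(ddof=1) == 0 and mix.std(ddof=1) == 0:
        return 0.0, 1.0
    t, p = sps.ttest_ind(co, mix, equal_var=True, alternative="greater")
    return float(t), float(p)


def _t_matrix(co: np.ndarray, mix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-tailed Student t over gene x replicate matrices."""
    import warnings

    with warnings.catch_warnings():
        # scipy warns about precision loss on rows of near-identical
        # counts; those rows are handled by the degenerate-variance
        # convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(co, mix, axis=1, equal_var=True, alternative="greater")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (co.std(axis=1, ddof=1) == 0) & (mix.std(axis=1, ddof=1) == 0)
    if degenerate.any():
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    return t, p


# ---------------------------------------------------------------------------
# Two-stage Benjamini-Krieger-Yekutieli FDR

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bky_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up FDR procedure (Benjamini-Krieger-Yekutieli).

    Stage one runs BH at level alpha' = alpha/(1+alpha) to estimate the
    number of true nulls m0 = m - r1; stage two runs BH at level
    alpha' * m/m0. Returns (q, reject) where q are adjusted values
    satisfying reject = (q <= alpha): q = BH-adjusted p x (1+alpha) x m0/m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise TransferomeError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise TransferomeError("alpha must lie in (0, 1)")
    m = p.size
    alpha_prime = alpha / (1.0 + alpha)
    bh = _bh_adjust(p)
    r1 = int((bh <= alpha_prime).sum())
    if r1 == m:
        return np.zeros(m), np.ones(m, dtype=bool)
    m0 = m - r1
    q = np.minimum(bh * (1.0 + alpha) * m0 / m, 1.0)
    return q, q <= alpha


# ---------------------------------------------------------------------------
# Transfer detection and percentage transfer

@dataclass
class TransferParams:
    fc_threshold: float = 2.0
    fdr_alpha: float = 0.05
    single_rpm_min: float = 100.0
    coculture_rpm_min: float = 10.0


def detect_transferred(
    rpm_foreign: pd.DataFrame,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_alpha: float = 0.05,
    min_rpm: float = 10.0,
) -> pd.DataFrame:
    """Robust-transfer detection: pre-filter, one-tailed t, BKY FDR.

    Genes must exceed ``min_rpm`` RPM in *all* co-culture replicates to
    enter the test; among those, robust = fold change > ``fc_threshold``
    and BKY q < ``fdr_alpha``. Fold change with a zero Mix mean is
    reported as +inf (no pseudocount); the pre-filter guards the numerator.
    """
    co_cols = list(design.loc[design["condition"] == "coculture", "sample"])
    mix_cols = list(design.loc[design["condition"] == "mix", "sample"])
    if len(co_cols) < 2 or len(mix_cols) < 2:
        raise TransferomeError("need >= 2 co-culture and >= 2 mix replicates")
    co = rpm_foreign.loc[:, co_cols].to_numpy(dtype=float)
    mix = rpm_foreign.loc[:, mix_cols].to_numpy(dtype=float)
    mean_co = co.mean(axis=1)
    mean_mix = mix.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(
            mean_mix > 0, mean_co / mean_mix,
            np.where(mean_co > 0, np.inf, np.nan),
        )
    prefilter = (co > min_rpm).all(axis=1)

    t = np.full(len(rpm_foreign), np.nan)
    p = np.full(len(rpm_foreign), np.nan)
    q = np.full(len(rpm_foreign), np.nan)
    if prefilter.any():
        t[prefilter], p[prefilter] = _t_matrix(co[prefilter], mix[prefilter])
        q[prefilter], _ = bky_adjust(p[prefilter], fdr_alpha)
    with np.errstate(invalid="ignore"):
        robust = prefilter & (fc > fc_threshold) & (q < fdr_alpha)

    return pd.DataFrame(
        {
            "mean_rpm_coculture": mean_co,
            "mean_rpm_mix": mean_mix,
            "fold_change": fc,
            "prefilter_pass": prefilter,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "robust": robust,
        },
        index=rpm_foreign.index,
    )


@dataclass
class PercentTransfer:
    """Per-gene percentage transfer, or the filters that excluded it."""

    value: float | None
    filtered: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return self.value is not None


def percent_transfer(
    mean_rpm_co: float,
    mean_rpm_mix: float,
    mean_rpm_single_donor: float,
    fc_threshold: float = 2.0,
    single_rpm_min: float = 100.0,
    coculture_rpm_min: float = 10.0,
) -> PercentTransfer:
    """Percentage transfer = (mean co RPM - mean Mix RPM) x 100 / donor RPM.

    Genes with donor single-culture RPM below ``single_rpm_min``,
    co-culture RPM below ``coculture_rpm_min``, or fold change below
    ``fc_threshold`` are excluded (strict inequalities, as the thresholds
    are printed); the failing rules are returned. A zero donor RPM on an
    otherwise unfiltered gene yields an undefined marker.
    """
    flags = []
    if mean_rpm_single_donor < single_rpm_min:
        flags.append("low_single_expression")
    if mean_rpm_co < coculture_rpm_min:
        flags.append("low_coculture_signal")
    fc = np.inf if mean_rpm_mix == 0 else mean_rpm_co / mean_rpm_mix
    if fc < fc_threshold:
        flags.append("low_fc")
    if flags:
        return PercentTransfer(None, tuple(flags))
    if mean_rpm_single_donor == 0:
        return PercentTransfer(None, ("undefined_zero_single",))
    return PercentTransfer(
        (mean_rpm_co - mean_rpm_mix) * 100.0 / mean_rpm_single_donor
    )


def build_transfer_table(
    rpm_foreign: pd.DataFrame,
    donor_single: pd.Series,
    design: pd.DataFrame,
    params: TransferParams | None = None,
) -> pd.DataFrame:
    """Full per-gene transfer table: detection + percentage transfer."""
    params = params or TransferParams()
    table = detect_transferred(
        rpm_foreign, design,
        fc_threshold=params.fc_threshold,
        fdr_alpha=params.fdr_alpha,
        min_rpm=params.coculture_rpm_min,
    )
    table["mean_rpm_single_donor"] = donor_single.reindex(table.index)
    single = table["mean_rpm_single_donor"].to_numpy(dtype=float)
    co = table["mean_rpm_coculture"].to_numpy(dtype=float)
    mix = table["mean_rpm_mix"].to_numpy(dtype=float)
    fc = table["fold_change"].to_numpy(dtype=float)
    table["low_single_expression"] = single < params.single_rpm_min
    table["low_coculture_signal"] = co < params.coculture_rpm_min
    with np.errstate(invalid="ignore"):
        table["low_fc"] = ~(fc >= params.fc_threshold)
    filtered = (
        table["low_single_expression"]
        | table["low_coculture_signal"]
        | table["low_fc"]
        | (single <= 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (co - mix) * 100.0 / single
    table["percent_transfer"] = np.where(filtered, np.nan, pct)
    return table


def median_percent_transfer(transfer_table: pd.DataFrame) -> dict[str, float]:
    """Median percentage transfer over unfiltered genes.

    Reports the median, its log10, and (because a log-scale distribution
    summary may equally be read as the median of per-gene logs) the median
    of per-gene log10 values over positive estimates.
    """
    values = transfer_table["percent_transfer"].dropna()
    if values.empty:
        raise TransferomeError("all genes filtered: median undefined")
    med = float(values.median())
    positive = values[values > 0]
    return {
        "median": med,
        "log10_median": math.log10(med) if med > 0 else float("nan"),
        "median_log10": (
            float(np.log10(positive).median()) if not positive.empty else float("nan")
        ),
        "n_genes": int(values.size),
    }


def spot_percent_transfer(
    mean_acceptor_spots: float, mean_donor_spots: float
) -> dict[str, float]:
    """Single-molecule FISH transfer percentage: 100 x acceptor / donor spots.

    Returns full precision and the value rounded to 2 significant figures
    (the convention used in human-readable reports).
    """
    if mean_donor_spots <= 0:
        raise TransferomeError("donor spot mean must be > 0")
    value = 100.0 * mean_acceptor_spots / mean_donor_spots
    if value == 0:
        rounded = 0.0
    else:
        rounded = round(value, -int(math.floor(math.log10(abs(value)))) + 1)
    return {"percent": value, "percent_2sf": rounded}


# ---------------------------------------------------------------------------
# Expression dependence and distribution fits

def expression_dependence(
    rpm_transferred,
    rpm_expression,
    log_transform: bool = True,
    ci_level: float = 0.99,
    pseudocount: float = 1.0,
) -> dict:
    """OLS of transferred signal on expression, with correlation coefficients.

    When ``log_transform`` both axes are log10(RPM + pseudocount). The
    confidence band is the pointwise mean-response interval at ``ci_level``
    from the t distribution, evaluated at the input x. Spearman is computed
    on the untransformed values (rank-invariant under the log anyway).
    """
    y_raw = np.asarray(rpm_transferred, dtype=float)
    x_raw = np.asarray(rpm_expression, dtype=float)
    if x_raw.size != y_raw.size or x_raw.size < 3:
        raise TransferomeError("need paired vectors of length >= 3")
    if log_transform:
        x = np.log10(x_raw + pseudocount)
        y = np.log10(y_raw + pseudocount)
    else:
        x, y = x_raw, y_raw
    if np.allclose(x, x[0]):
        raise TransferomeError("constant x: slope and correlations undefined")
    fit = sps.linregress(x, y)
    rho = sps.spearmanr(x_raw, y_raw).statistic
    n = x.size
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, df=n - 2)
    half = tcrit * np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    yhat = fit.intercept + fit.slope * x
    return {
        "pearson": float(fit.rvalue),
        "spearman": float(rho),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "x": x,
        "fitted": yhat,
        "ci_low": yhat - half,
        "ci_high": yhat + half,
        "ci_level": ci_level,
    }


def fit_log_gaussian(
    rpm_co_vector, rpm_mix_vector, pseudocount: float = 1.0
) -> dict:
    """Gaussian fits to log10(RPM + pseudocount) per group, plus shift p.

    The rightward shift of the co-culture distribution (transfer of most of
    the transcriptome) is assessed by a two-sample t-test on the per-gene
    log values.
    """
    if pseudocount <= 0:
        raise TransferomeError("pseudocount must be > 0")
    out = {}
    logs = {}
    for name, vec in (("coculture", rpm_co_vector), ("mix", rpm_mix_vector)):
        v = np.asarray(vec, dtype=float)
        if (v > 0).sum() < 3:
            raise TransferomeError(f"{name}: fewer than 3 positive entries")
        lv = np.log10(v + pseudocount)
        mu, sd = sps.norm.fit(lv)
        out[name] = {"mean": float(mu), "sd": float(sd)}
        logs[name] = lv
    t, p = sps.ttest_ind(logs["coculture"], logs["mix"], equal_var=True)
    out["shift"] = {
        "delta_log10": out["coculture"]["mean"] - out["mix"]["mean"],
        "t": float(t),
        "p_value": float(p) if not math.isnan(p) else 1.0,
    }
    return out


def hypergeometric_overlap(universe_size: int, set_a, set_b) -> dict:
    """Upper-tail hypergeometric overlap test P(X >= observed overlap)."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise TransferomeError("set larger than universe")
    overlap = len(a & b)
    p = float(sps.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return {"overlap": overlap, "p_value": min(p, 1.0)}


def hypergeometric_overlap_sets(universe, set_a, set_b) -> dict:
    """Overlap test with explicit universe membership validation."""
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    outside = (a | b) - uni
    if outside:
        raise TransferomeError(
            f"set element(s) outside universe: {sorted(outside)[:5]}"
        )
    return hypergeometric_overlap(len(uni), a, b)


# ---------------------------------------------------------------------------
# Post-hoc differential-expression thresholding

def filter_de_genes(
    de_table: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    min_count: float = 50.0,
    min_samples: int = 2,
) -> tuple[set, set]:
    """Threshold an upstream DE table into up/down gene sets.

    up: log2fc >= lfc_min, padj < alpha, and >= min_count normalized counts
    in >= min_samples samples; down mirrors with log2fc <= -lfc_min.
    """
    for col in ("gene", "log2fc", "padj"):
        if col not in de_table.columns:
            raise TransferomeError(f"missing column '{col}'")
    count_cols = [
        c for c in de_table.columns if c not in ("gene", "log2fc", "padj")
    ]
    if not count_cols:
        raise TransferomeError("missing normalized-count columns")
    counts_ok = (de_table[count_cols] >= min_count).sum(axis=1) >= min_samples
    sig = (de_table["padj"] < alpha) & counts_ok
    up = set(de_table.loc[sig & (de_table["log2fc"] >= lfc_min), "gene"])
    down = set(de_table.loc[sig & (de_table["log2fc"] <= -lfc_min), "gene"])
    return up, down
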