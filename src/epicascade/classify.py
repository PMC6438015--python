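"""Tumor-vs-normal classification metrics.

AUC via the rank (concordant-pair) formulation with DeLong confidence
intervals, Youden-optimal cutoffs with sensitivity/specificity, the
beta-to-M logit transform for methylation probes, and logistic regression
fit by iteratively reweighted least squares with Wald tests and odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class PerfectSeparationError(RuntimeError):
    """Raised when logistic-regression classes are perfectly separable."""

    def __init__(self, message: str, coefficients: np.ndarray | None = None):
        super().__init__(message)
        self.coefficients = coefficients


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores, labels) -> RocResult:
    """AUC (ties get half credit) with a DeLong 95% confidence interval.

    ``labels`` are binary with 1 = positive class (tumor); AUC is the
    probability that a positive outranks a negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return RocResult(auc=float(auc), ci95=(float(lo), float(hi)))


def optimal_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores.  When the
    marker is anti-informative (AUC < 0.5) the decision direction flips so
    that low scores call the positive class.  Ties in J break toward higher
    specificity, then the lower cutoff.  Returns (cutoff, sens, spec).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("constant scores admit no informative cutoff")
    auc = roc_auc(scores, labels).auc
    positive_high = auc >= 0.5
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in cuts:
        if positive_high:
            sens = float((pos > c).mean())
            spec = float((neg <= c).mean())
        else:
            sens = float((pos <= c).mean())
            spec = float((neg > c).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -c)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec))
    return best[1]


def m_value(beta, epsilon: float = 1e-6):
    """Logit (base-2) transform of methylation beta values.

    M = log2(b / (1 - b)) with b clipped to [epsilon, 1 - epsilon].
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log2(clipped / (1.0 - clipped))
    return float(out) if np.isscalar(beta) else out


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference per coefficient."""

    coefficients: pd.Series
    standard_errors: pd.Series
    wald_p: pd.Series
    odds_ratio: pd.Series
    or_ci95: pd.DataFrame  # columns lo, hi
    converged: bool
    n_iterations: int
    log_likelihood: float
    llf_trajectory: list[float] = field(default_factory=list)


def logistic_fit(
    design: pd.DataFrame | np.ndarray,
    labels,
    max_iter: int = 50,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Raises PerfectSeparationError when the classes are separable (the MLE
    diverges); non-convergence within ``max_iter`` is reported via the
    ``converged`` flag rather than silently returned.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant non-intercept column {names[j]!r}")
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")

    beta = np.zeros(p)
    llf_path: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        llf = float(np.sum(y * np.log(mu + 1e-300) +
                           (1 - y) * np.log(1 - mu + 1e-300)))
        llf_path.append(llf)
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 30 and np.all((mu > 0.5) == (y == 1)):
            raise PerfectSeparationError(
                "perfect separation: the maximum-likelihood estimate diverges",
                coefficients=beta.copy(),
            )
        xtwx = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                f"singular information matrix at iteration {it}: {exc}",
                coefficients=beta.copy(),
            ) from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    llf = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    llf_path.append(llf)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald = 2.0 * sps.norm.sf(np.abs(z))
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    return LogisticFit(
        coefficients=coef,
        standard_errors=se_s,
        wald_p=pd.Series(wald, index=names),
        odds_ratio=np.exp(coef),
        or_ci95=pd.DataFrame(
            {"lo": np.exp(coef - 1.96 * se_s), "hi": np.exp(coef + 1.96 * se_s)}
        ),
        converged=converged,
        n_iterations=len(llf_path) - 1,
        log_likelihood=llf,
        llf_trajectory=llf_path,
    )


def _feature_row(name: str, values: np.ndarray, labels: np.ndarray) -> dict:
    roc = roc_auc(values, labels)
    cutoff, sens, spec = optimal_cutoff(values, labels)
    row = {
        "feature": name,
        "auc": roc.auc,
        "auc_ci_lo": roc.ci95[0],
        "auc_ci_hi": roc.ci95[1],
        "cutoff": cutoff,
        "sensitivity": sens,
        "specificity": spec,
    }
    try:
        fit = logistic_fit(pd.DataFrame({name: values}), labels)
        row.update(
            uni_p=fit.wald_p[name],
            uni_or=fit.odds_ratio[name],
            uni_or_lo=fit.or_ci95.loc[name, "lo"],
            uni_or_hi=fit.or_ci95.loc[name, "hi"],
            uni_converged=fit.converged,
        )
    except PerfectSeparationError:
        row.update(uni_p=np.nan, uni_or=np.nan, uni_or_lo=np.nan,
                   uni_or_hi=np.nan, uni_converged=False)
    return row


def _multivariate_table(matrix: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    try:
        fit = logistic_fit(matrix, labels)
    except PerfectSeparationError:
        return pd.DataFrame(
            index=matrix.columns,
            columns=["multi_p", "multi_or", "multi_or_lo", "multi_or_hi"],
            dtype=float,
        )
    rows = fit.or_ci95.drop(index="intercept")
    return pd.DataFrame(
        {
            "multi_p": fit.wald_p.drop(index="intercept"),
            "multi_or": fit.odds_ratio.drop(index="intercept"),
            "multi_or_lo": rows["lo"],
            "multi_or_hi": rows["hi"],
        }
    )


def run_classification_suite(
    panel_genes: list[str],
    expr: pd.DataFrame,
    probe_betas: pd.DataFrame,
    panel_probes: list[str],
    clinical: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-gene and per-probe tumor/normal classification tables.

    Expression features use raw normalized values; probe features use
    M-values.  Univariate metrics (ROC, cutoff, logistic fit) are computed
    per feature; one joint multivariate logistic fit spans all panel genes
    and another all panel probes.  Probes with no beta values are skipped
    and listed under 'skipped'.
    """
    clin = clinical.set_index("sample_id")
    samples = [s for s in expr.columns if s in clin.index]
    labels = (clin.loc[samples, "tissue"] == "tumor").astype(int).to_numpy()
    gene_rows = []
    for gene in panel_genes:
        values = expr.loc[gene, samples].to_numpy(dtype=float)
        gene_rows.append(_feature_row(gene, values, labels))
    gene_table = (
        pd.DataFrame(gene_rows).set_index("feature")
        if gene_rows else pd.DataFrame()
    )

    skipped = []
    probe_rows = []
    probe_samples = [s for s in probe_betas.columns if s in clin.index]
    probe_labels = (
        (clin.loc[probe_samples, "tissue"] == "tumor").astype(int).to_numpy()
    )
    mvals = {}
    for probe in panel_probes:
        series = probe_betas.loc[probe, probe_samples]
        if series.isna().all():
            skipped.append(probe)
            continue
        values = m_value(series.to_numpy(dtype=float))
        mvals[probe] = values
        probe_rows.append(_feature_row(probe, values, probe_labels))
    probe_table = (
        pd.DataFrame(probe_rows).set_index("feature")
        if probe_rows else pd.DataFrame()
    )

    out = {
        "genes": gene_table,
        "probes": probe_table,
        "skipped_probes": pd.DataFrame({"probe_id": skipped}),
    }
    if len(panel_genes) >= 1 and gene_rows:
        mat = expr.loc[panel_genes, samples].T.astype(float)
        out["multivariate_genes"] = _multivariate_table(mat, labels)
    if mvals:
        mat = pd.DataFrame(mvals, index=probe_samples)
        out["multivariate_probes"] = _multivariate_table(mat, probe_labels)
    return out
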