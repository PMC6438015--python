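"""Two-group negative-binomial differential expression on gene counts.

Pipeline: CPM expression filter, median-of-ratios size factors, common
dispersion by method of moments, and an exact conditional test on the
per-condition sums of library-size-equalized pseudo-counts.  The variance
model is var = mu + phi * mu^2; phi = 0 collapses the conditional null to a
binomial split of the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "filter_expressed",
    "size_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "classify_de",
    "DEResult",
]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    fold_change: float
    p_value: float
    status: str  # down | up | ns


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.Index:
    """Genes with counts-per-million >= min_cpm in >= min_samples samples."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lib = counts.sum(axis=0).astype(float)
    lib = lib.replace(0, np.nan)
    cpm = counts.divide(lib, axis=1) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample drop out of the reference; if none
    remain the factors fall back to relative library sizes.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        log_geo = np.log(mat[positive]).mean(axis=1, keepdims=True)
        ratios = np.exp(np.log(mat[positive]) - log_geo)
        factors = np.median(ratios, axis=0)
    else:
        lib = mat.sum(axis=0)
        factors = lib / lib.mean()
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: dict[str, list[str]]
) -> float:
    """Common NB dispersion via method of moments on normalized counts.

    Within each condition, per-gene dispersion is (s^2 - m) / m^2 from the
    normalized-count mean and variance; the common value is the across-gene
    mean, floored at 0.  Groups of size 1 contribute nothing.
    """
    sf = size_factors(counts)
    norm = counts.divide(sf, axis=1)
    contribs = []
    for samples in groups.values():
        if len(samples) < 2:
            continue
        sub = norm[samples].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        contribs.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not contribs:
        return 0.0
    pooled = np.concatenate(contribs)
    if pooled.size == 0:
        return 0.0
    return float(max(0.0, pooled.mean()))


def _exact_conditional_p(
    s1: int, s2: int, n1: int, n2: int, dispersion: float
) -> float:
    """Two-sided exact test of an s1:s2 split of the total pseudo-count sum.

    Conditional on t = s1 + s2, the group-1 sum y has probability
    proportional to NB(y; n1*mu, phi/n1) * NB(t-y; n2*mu, phi/n2) with
    mu = t/(n1+n2); p is the sum of probabilities <= that of the observed
    split.  phi = 0 reduces to Binomial(t, n1/(n1+n2)).
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if dispersion <= 0:
        logp = sps.binom.logpmf(y, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / dispersion, n2 / dispersion
        logp = sps.nbinom.logpmf(y, r1, r1 / (r1 + n1 * mu)) + sps.nbinom.logpmf(
            t - y, r2, r2 / (r2 + n2 * mu)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return float(min(1.0, probs[probs <= probs[s1] * (1 + 1e-12)].sum()))


def nb_exact_test(
    counts: pd.DataFrame,
    ko_samples: list[str],
    parental_samples: list[str],
    dispersion: float | str = "auto",
    size_factors_override: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene exact NB test of KO vs parental counts.

    Returns a DataFrame indexed by gene with columns fold_change (KO over
    parental, normalized), p_value, and all_zero flag.  'auto' dispersion is
    the common method-of-moments estimate.  ``size_factors_override`` lets a
    caller normalize by externally known depths (e.g. full-library sizes for
    capture-seq region counts) instead of median-of-ratios.
    """
    for s in ko_samples + parental_samples:
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} not in count matrix")
    sub = counts[ko_samples + parental_samples]
    if (sub.sum(axis=0) <= 0).any():
        raise ValueError("zero-depth library")
    if size_factors_override is not None:
        sf = size_factors_override.reindex(sub.columns).astype(float)
        if sf.isna().any() or (sf <= 0).any():
            raise ValueError("size_factors_override must be positive for all samples")
        sf = sf / np.exp(np.log(sf).mean())  # geometric-mean centering
    else:
        sf = size_factors(sub)
    if dispersion == "auto":
        phi = estimate_common_dispersion(
            sub, {"ko": ko_samples, "parental": parental_samples}
        )
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be >= 0")
    norm = sub.divide(sf, axis=1)
    n1, n2 = len(ko_samples), len(parental_samples)
    # equalized pseudo-counts: normalized counts rounded back to integers
    pseudo_ko = norm[ko_samples].sum(axis=1).round().astype(int)
    pseudo_par = norm[parental_samples].sum(axis=1).round().astype(int)
    mean_ko = norm[ko_samples].mean(axis=1)
    mean_par = norm[parental_samples].mean(axis=1)
    fold = (mean_ko + 0.5) / (mean_par + 0.5)
    rows = []
    for gene in sub.index:
        s1, s2 = int(pseudo_ko[gene]), int(pseudo_par[gene])
        all_zero = (s1 + s2) == 0
        p = 1.0 if all_zero else _exact_conditional_p(s1, s2, n1, n2, phi)
        rows.append(
            {
                "gene_id": gene,
                "fold_change": 1.0 if all_zero else float(fold[gene]),
                "p_value": p,
                "all_zero": all_zero,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out.attrs["dispersion"] = phi
    out.attrs["normalization"] = "median-of-ratios"
    return out


def classify_de(
    results: pd.DataFrame,
    alpha: float = 0.05,
    down_fc: float = 1 / 1.5,
    up_fc: float = 1.5,
) -> pd.DataFrame:
    """Attach a status column: down / up / ns at the given thresholds.

    The default scheme is the 1.5-fold rule; the candidate cascade instead
    uses down_fc = 0.75 with up_fc disabled (pass up_fc = inf).
    """
    sig = results["p_value"] < alpha
    down = sig & (results["fold_change"] < down_fc)
    up = sig & (results["fold_change"] > up_fc)
    out = results.copy()
    out["status"] = np.where(down, "down", np.where(up, "up", "ns"))
    return out
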