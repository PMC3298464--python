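"""Methylated-window calling by three methods and their agreement.

Three callers over the same 1 kb window universe:

* **RPKM / empirical FDR** — the per-window difference between sample
  RPKM and the mean input RPKM is compared with the null distribution of
  input-vs-input differences; the cutoff is the smallest grid value at
  which the sample comparison yields ``ratio`` (default 100) significant
  windows for every one in the input-input comparison, i.e. a 1% FDR.
* **CPPD** — upper-tail cumulative Poisson probability of the window's
  MeDIP count given its normalized input count, significant below 1e-4.
* **Negative binomial** — same comparison with an NB tail whose
  dispersion is fit per tissue from the variance across biological
  replicates (variance = mu + mu^2/r), at 1e-4 (~5% FDR) or 1e-3
  (~20% FDR).

Input normalization rescales input counts to each MeDIP sample's depth
and floors every window's expectation at the genome-average normalized
input (the floor only ever raises the expectation, making low-coverage
windows conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class NoCutoffError(RuntimeError):
    """No grid cutoff achieves the requested sample:null ratio."""


@dataclass
class EmpiricalFdrResult:
    cutoff_rpkm: float
    ratio_required: int
    grid_step: float
    n_sample_exceed: int
    n_null_exceed: float
    grid: np.ndarray = field(default=None, repr=False)
    sample_exceed: np.ndarray = field(default=None, repr=False)
    null_exceed: np.ndarray = field(default=None, repr=False)


@dataclass
class CallSet:
    """Windows (or features) called methylated by one method, one tissue."""

    method: str
    tissue: str
    mask: np.ndarray  # boolean over the universe
    threshold: float
    universe_ids: np.ndarray | None = None

    @property
    def n_called(self) -> int:
        return int(self.mask.sum())

    @property
    def called_window_ids(self) -> set:
        ids = (np.arange(self.mask.size) if self.universe_ids is None
               else np.asarray(self.universe_ids))
        return set(ids[self.mask].tolist())


@dataclass
class NBFit:
    r: float
    mu_bar: float
    v_bar: float
    n_strata: int = 1


# ---------------------------------------------------------------------------
# empirical-FDR RPKM method

def input_difference_null(input_rpkms: np.ndarray) -> np.ndarray:
    """Absolute per-window differences over all ordered input-lane pairs.

    Rows of the returned array are pairs; exceedance counts are averaged
    across pairs to form the null.
    """
    m = np.asarray(input_rpkms, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need >= 2 input samples on the same window set")
    diffs = []
    for i in range(m.shape[0]):
        for j in range(m.shape[0]):
            if i != j:
                diffs.append(np.abs(m[i] - m[j]))
    return np.vstack(diffs)


def empirical_fdr_cutoff(sample_rpkm: np.ndarray, input_rpkms: np.ndarray,
                         ratio: int = 100, grid_step: float = 0.01,
                         keep_grid: bool = False) -> EmpiricalFdrResult:
    """Smallest RPKM cutoff giving ``ratio`` sample calls per null call.

    The null is the pooled distribution of input-input differences,
    exceedance counts averaged across ordered lane pairs; the sample
    statistic is sample RPKM minus the mean input RPKM per window.  A
    null exceedance of zero satisfies the rule whenever the sample
    exceedance is positive.
    """
    sample_rpkm = np.asarray(sample_rpkm, dtype=float)
    null = input_difference_null(input_rpkms)
    n_pairs = null.shape[0]
    sample_diff = sample_rpkm - np.asarray(input_rpkms, dtype=float).mean(axis=0)

    null_sorted = np.sort(null.ravel())
    sample_sorted = np.sort(sample_diff)
    top = max(sample_sorted[-1] if sample_sorted.size else 0.0, 0.0)
    grid = np.arange(grid_step, top + 2 * grid_step, grid_step)
    if grid.size == 0:
        raise NoCutoffError("no positive sample differences; nothing to call")

    ns = sample_sorted.size - np.searchsorted(sample_sorted, grid, side="left")
    nn = (null_sorted.size - np.searchsorted(null_sorted, grid, side="left")) / n_pairs
    ok = (ns > 0) & (ns >= ratio * nn)
    if not ok.any():
        raise NoCutoffError(
            "no cutoff achieves FDR target "
            f"(ratio {ratio}; max sample diff {top:.3g}, "
            f"null max {null_sorted[-1] if null_sorted.size else 0:.3g})"
        )
    k = int(np.argmax(ok))
    return EmpiricalFdrResult(
        cutoff_rpkm=float(grid[k]),
        ratio_required=ratio,
        grid_step=grid_step,
        n_sample_exceed=int(ns[k]),
        n_null_exceed=float(nn[k]),
        grid=grid if keep_grid else None,
        sample_exceed=ns if keep_grid else None,
        null_exceed=nn if keep_grid else None,
    )


def call_rpkm(sample_rpkm: np.ndarray, input_rpkms: np.ndarray, cutoff: float,
              tissue: str = "", universe_ids=None) -> CallSet:
    """Call windows whose sample-minus-mean-input RPKM difference >= cutoff."""
    diff = np.asarray(sample_rpkm, dtype=float) - np.asarray(
        input_rpkms, dtype=float).mean(axis=0)
    return CallSet("RPKM", tissue, diff >= cutoff, float(cutoff),
                   universe_ids=universe_ids)


# ---------------------------------------------------------------------------
# count normalization and Poisson / NB tails

def normalize_input(input_counts: np.ndarray, input_total: float,
                    sample_total: float) -> np.ndarray:
    """Scale input counts to the MeDIP sample depth and apply the mean floor.

    lambda_w = input_w * sample_total/input_total, then raised to the
    genome-average normalized count wherever it falls below it.
    """
    if input_total <= 0 or sample_total <= 0:
        raise ValueError("totals must be positive")
    lam = np.asarray(input_counts, dtype=float) * (sample_total / input_total)
    return np.maximum(lam, lam.mean())


def cppd_pvalue(k, lam):
    """P(X >= k | Poisson(lambda)); fractional counts are floored."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    k = np.floor(np.asarray(k, dtype=float)).astype(int)
    return stats.poisson.sf(k - 1, lam)


def call_cppd(counts, lams, alpha: float = 1e-4, tissue: str = "",
              universe_ids=None) -> CallSet:
    """Call windows with CPPD upper-tail probability strictly below alpha."""
    p = cppd_pvalue(counts, lams)
    return CallSet("CPPD", tissue, p < alpha, float(alpha),
                   universe_ids=universe_ids)


def fit_nb(replicate_counts: np.ndarray, n_strata: int = 1) -> NBFit:
    """Method-of-moments NB dispersion from replicate window counts.

    ``replicate_counts`` is windows x replicates.  Per window the mean
    and (ddof=1) variance across replicates are taken; pooling averages
    them over windows (optionally within mean-count strata) and solves
    variance = mu + mu^2/r.  When the pooled variance does not exceed
    the mean, r = inf (the NB degenerates to Poisson).
    """
    m = np.asarray(replicate_counts, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("cannot estimate dispersion from a single replicate")
    mu_w = m.mean(axis=1)
    v_w = m.var(axis=1, ddof=1)

    if n_strata <= 1:
        strata = np.zeros(mu_w.size, dtype=int)
    else:
        qs = np.quantile(mu_w, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata = np.searchsorted(qs, mu_w)

    num = 0.0
    den = 0.0
    for s in np.unique(strata):
        sel = strata == s
        mu_bar = mu_w[sel].mean()
        v_bar = v_w[sel].mean()
        n = int(sel.sum())
        num += n * mu_bar ** 2
        den += n * (v_bar - mu_bar)
    mu_all, v_all = float(mu_w.mean()), float(v_w.mean())
    if den <= 0:
        return NBFit(r=np.inf, mu_bar=mu_all, v_bar=v_all, n_strata=n_strata)
    return NBFit(r=float(num / den), mu_bar=mu_all, v_bar=v_all,
                 n_strata=n_strata)


def nb_pvalue(k, mu, r):
    """P(X >= k | NB(mean mu, dispersion r)); r -> inf gives the Poisson tail."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.isinf(r):
        return cppd_pvalue(k, mu)
    if r <= 0:
        raise ValueError("dispersion r must be positive")
    k = np.floor(np.asarray(k, dtype=float)).astype(int)
    p = r / (r + mu)  # success probability in scipy's parametrization
    return stats.nbinom.sf(k - 1, r, p)


def call_nb(counts, lams, r: float, alpha: float = 1e-4, tissue: str = "",
            universe_ids=None) -> CallSet:
    p = nb_pvalue(counts, lams, r)
    return CallSet("NB", tissue, p < alpha, float(alpha),
                   universe_ids=universe_ids)


# ---------------------------------------------------------------------------
# agreement

def agreement_percent(n_common: int, n_called: int) -> float:
    """100 x common/called to one decimal (the 'Agreement NB' statistic)."""
    if n_called == 0:
        raise ZeroDivisionError("agreement undefined for an empty call set")
    return round(100.0 * n_common / n_called, 1)


def method_agreement(callsets: list[CallSet]) -> dict:
    """Agreement among methods on one window universe.

    ``agreement_all`` = |called by all| / |called by any|;
    ``agreement_nb`` = 100 x |common to all| / |NB calls|, one decimal
    (None when NB called nothing).
    """
    if not callsets:
        raise ValueError("no call sets")
    n = callsets[0].mask.size
    if any(cs.mask.size != n for cs in callsets):
        raise ValueError("call sets are on different window universes")
    all_mask = np.logical_and.reduce([cs.mask for cs in callsets])
    any_mask = np.logical_or.reduce([cs.mask for cs in callsets])
    n_all, n_any = int(all_mask.sum()), int(any_mask.sum())
    out = {
        "n_common_all": n_all,
        "n_any": n_any,
        "agreement_all": n_all / n_any if n_any else np.nan,
        "agreement_nb": None,
    }
    nb = [cs for cs in callsets if cs.method == "NB"]
    if nb and nb[0].n_called > 0:
        out["agreement_nb"] = agreement_percent(n_all, nb[0].n_called)
    return out
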