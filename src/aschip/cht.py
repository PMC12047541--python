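"""The combined haplotype test (CHT) for allelic imbalance in TF binding.

Two likelihood components share one effect parameter ``p``, the probability
that a sequenced fragment originates from the haplotype carrying the test
variant's ALT allele:

* an allele-specific beta-binomial over the phased heterozygous samples,
  with ``k = as_alt``, ``n = as_ref + as_alt`` and success probability ``p``;
* a beta-negative-binomial over every sample's total region count ``T``,
  whose mean scales the adjusted expectation ``E`` by the genotype:
  ``mu = E * (c_ref * (1 - p) + c_alt * p)`` with ``(c_ref, c_alt)`` equal to
  (2, 0), (1, 1), (0, 2) for 0, 1, 2 ALT copies.

Under the null ``p = 0.5`` (equal haplotype output, genotype-independent
depth).  Significance comes from a 1-df likelihood-ratio test; effect sizes
are summarized as the reference-allele bias ``alpha/(alpha+beta) = 1 - p``
and the allelic imbalance ``AI = |0.5 - alpha/(alpha+beta)|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln

from .counts import RegionTest

logger = logging.getLogger(__name__)

_P_LO, _P_HI = 1e-6, 1.0 - 1e-6
_XATOL = 1e-8


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def bb_loglik(k, n, p: float, rho: float):
    """Beta-binomial log-likelihood with mean ``p`` and overdispersion ``rho``.

    ``rho`` is the intraclass correlation in [0, 1); ``rho -> 0`` recovers the
    binomial log-pmf exactly.  Vectorized over ``k``/``n``.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p < 1.0) or not (0.0 <= rho < 1.0):
        raise ValueError(f"p={p}, rho={rho} out of domain")
    choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    if rho < 1e-8:
        # binomial limit; the beta-function form loses precision to
        # cancellation long before rho gets this small
        return choose + k * np.log(p) + (n - k) * np.log1p(-p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return choose + betaln(k + a, n - k + b) - betaln(a, b)


def bnb_loglik(t, mu, phi: float, rho_extra: float = 0.0):
    """Beta-negative-binomial log-likelihood with mean ``mu``.

    ``phi`` is the gamma (negative-binomial) dispersion: variance grows as
    ``mu + mu^2/phi``, so ``phi -> inf`` recovers the Poisson log-pmf.
    ``rho_extra`` in [0, 1) adds a beta layer on the NB success probability
    while preserving the mean; 0 degenerates to the plain negative binomial.
    """
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if np.any(mu <= 0) or phi <= 0 or not (0.0 <= rho_extra < 1.0):
        raise ValueError("mu, phi must be positive; rho_extra in [0,1)")
    if phi > 1e8:
        # Poisson limit (variance -> mean); exact for phi = inf and more
        # accurate than the gamma-mixture form for any larger phi
        return t * np.log(mu) - mu - gammaln(t + 1)
    r = phi
    comb = gammaln(t + r) - gammaln(t + 1) - gammaln(r)
    if rho_extra == 0.0:
        logq = np.log(r) - np.log(r + mu)
        log1mq = np.log(mu) - np.log(r + mu)
        return comb + r * logq + t * log1mq
    a = 1.0 + 1.0 / rho_extra
    b = mu * (a - 1.0) / r  # keeps E[t] = mu for any rho_extra
    return comb + betaln(a + r, b + t) - betaln(a, b)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dispersions:
    rho_as: float  # beta-binomial overdispersion in [0, 1)
    phi_bnb: float  # depth dispersion > 0
    rho_bnb: float = 0.0  # optional beta layer of the BNB

    def __iter__(self):
        return iter((self.rho_as, self.phi_bnb, self.rho_bnb))


DEFAULT_DISPERSIONS = Dispersions(rho_as=0.01, phi_bnb=100.0)


def estimate_dispersions(
    region_tests: Sequence[RegionTest],
    min_regions: int = 50,
    fallback: Dispersions = DEFAULT_DISPERSIONS,
) -> Dispersions:
    """Genome-wide null MLE of the two overdispersions (alpha = beta per region).

    Deterministic given the data; with fewer than ``min_regions`` tests the
    configured fallback is returned with a warning (too little information
    for a stable genome-wide estimate).
    """
    unique = {rt.region_id: rt for rt in region_tests}.values()
    if len(unique) < min_regions:
        logger.warning(
            "estimate_dispersions: %d regions < %d, using fallback %s",
            len(unique), min_regions, fallback,
        )
        return fallback
    ks, ns, ts, es = [], [], [], []
    for rt in unique:
        het = rt.het
        n = (rt.as_ref + rt.as_alt)[het]
        ks.append(rt.as_alt[het][n > 0])
        ns.append(n[n > 0])
        ok = rt.E > 0
        ts.append(rt.T[ok])
        es.append(rt.E[ok])
    k = np.concatenate(ks)
    n = np.concatenate(ns)
    t = np.concatenate(ts)
    e = np.concatenate(es)

    def neg_as(logit_rho):
        rho = 1.0 / (1.0 + np.exp(-logit_rho))
        return -bb_loglik(k, n, 0.5, rho).sum()

    res = optimize.minimize_scalar(neg_as, bounds=(-12, 6), method="bounded",
                                   options={"xatol": 1e-8})
    rho_as = float(1.0 / (1.0 + np.exp(-res.x)))

    def neg_bnb(log_phi):
        return -bnb_loglik(t, e, float(np.exp(log_phi))).sum()

    res = optimize.minimize_scalar(neg_bnb, bounds=(np.log(1e-2), np.log(1e8)),
                                   method="bounded", options={"xatol": 1e-8})
    phi = float(np.exp(res.x))
    return Dispersions(rho_as=rho_as, phi_bnb=phi)


# ---------------------------------------------------------------------------
# Per-test fit
# ---------------------------------------------------------------------------

@dataclass
class CHTResult:
    region_id: str
    variant_id: str
    component: str  # full | as | bnb
    alpha: float
    beta: float
    ll_null: float
    ll_alt: float
    lrt_stat: float
    p_value: float
    n_het: int
    converged: bool

    @property
    def ref_bias(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def ai(self) -> float:
        return abs(0.5 - self.ref_bias)


def _loglik_fn(rt: RegionTest, disp: Dispersions, component: str,
               g=None, phase=None):
    """Log-likelihood in the shared effect parameter p (ALT-haplotype share)."""
    phase = rt.phase if phase is None else phase
    g = rt.g if g is None else g
    het = phase[:, 0] != phase[:, 1]
    ref_on_m = phase[:, 0] == 0
    as_ref = np.where(ref_on_m, rt.as_m, rt.as_p)[het]
    as_alt = np.where(ref_on_m, rt.as_p, rt.as_m)[het]
    n = as_ref + as_alt
    k = as_alt[n > 0]
    n = n[n > 0]
    ok = rt.E > 0
    t = rt.T[ok]
    e = rt.E[ok]
    c_alt = g[ok].astype(float)
    c_ref = 2.0 - c_alt
    use_as = component in ("full", "as") and n.size > 0
    use_bnb = component in ("full", "bnb") and t.size > 0

    def ll(p: float) -> float:
        total = 0.0
        if use_as:
            total += float(bb_loglik(k, n, p, disp.rho_as).sum())
        if use_bnb:
            mu = e * (c_ref * (1.0 - p) + c_alt * p)
            total += float(bnb_loglik(t, mu, disp.phi_bnb, disp.rho_bnb).sum())
        return total

    informative = use_as or (use_bnb and len(set(g[ok].tolist())) > 1)
    return ll, int(n.size), informative


def fit_cht(
    rt: RegionTest,
    dispersions: Dispersions = DEFAULT_DISPERSIONS,
    component: str = "full",
    g=None,
    phase=None,
) -> CHTResult | None:
    """Fit null (p = 0.5) and alternative (free p) models for one region test.

    Returns None for non-informative tests (no heterozygous sample and no
    genotype contrast in depth).  On optimizer non-convergence the result is
    flagged and assigned the conservative p-value 1.
    """
    ll, n_het, informative = _loglik_fn(rt, dispersions, component, g=g, phase=phase)
    if not informative:
        return None
    ll_null = ll(0.5)
    res = optimize.minimize_scalar(
        lambda p: -ll(p), bounds=(_P_LO, _P_HI), method="bounded",
        options={"xatol": _XATOL},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    p_hat = float(res.x) if converged else 0.5
    ll_alt = ll(p_hat)
    if ll_alt < ll_null:  # optimizer tolerance: the null is nested
        p_hat, ll_alt = 0.5, ll_null
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p_value = float(stats.chi2.sf(lrt, df=1)) if converged else 1.0
    scale = max(1.0, float(np.sum(rt.as_ref[rt.het] + rt.as_alt[rt.het])))
    return CHTResult(
        region_id=rt.region_id, variant_id=rt.variant.id, component=component,
        alpha=scale * (1.0 - p_hat), beta=scale * p_hat,
        ll_null=ll_null, ll_alt=ll_alt, lrt_stat=lrt,
        p_value=min(1.0, max(p_value, np.nextafter(0, 1))),
        n_het=n_het, converged=converged,
    )


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------

def run_cht(
    region_tests: Sequence[RegionTest],
    dispersions: Dispersions | None = None,
    components: Iterable[str] = ("full", "as", "bnb"),
    permute: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the CHT (and its AS-only / BNB-only components) over all tests.

    ``permute`` shuffles the per-sample genotype-and-phase blocks of each test
    variant (seeded) while leaving the counts with their samples — the
    empirical null used for calibration.  BH FDR is computed across all
    tested variants within each component.
    """
    if dispersions is None:
        dispersions = estimate_dispersions(region_tests)
    rng = np.random.default_rng(seed)
    rows = []
    for rt in region_tests:
        g, phase = rt.g, rt.phase
        if permute:
            perm = rng.permutation(len(rt.samples))
            g, phase = rt.g[perm], rt.phase[perm]
        for component in components:
            res = fit_cht(rt, dispersions, component, g=g, phase=phase)
            if res is None:
                continue
            rows.append({
                "region_id": res.region_id, "variant_id": res.variant_id,
                "component": res.component, "alpha": res.alpha, "beta": res.beta,
                "ref_bias": res.ref_bias, "ai": res.ai,
                "ll_null": res.ll_null, "ll_alt": res.ll_alt,
                "lrt_stat": res.lrt_stat, "p_value": res.p_value,
                "n_het": res.n_het, "converged": res.converged,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    from statsmodels.stats.multitest import multipletests

    df["fdr"] = np.nan
    for component, idx in df.groupby("component").groups.items():
        df.loc[idx, "fdr"] = multipletests(df.loc[idx, "p_value"], method="fdr_bh")[1]
    return df


def significant_set(
    results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    min_ai: float = 0.1,
    component: str = "full",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant variants (fdr < threshold and AI > min_ai) and imbalanced peaks.

    A peak (region) is imbalanced iff it has at least one significant variant;
    its top variant is the minimum-p one (ties: largest AI, then leftmost
    variant id).
    """
    sub = results[results["component"] == component].copy()
    sig = sub[(sub["fdr"] < fdr_threshold) & (sub["ai"] > min_ai)].copy()
    if sig.empty:
        return sig, pd.DataFrame(columns=["region_id", "variant_id"])
    sig = sig.assign(_coord=sig["variant_id"].map(_variant_coord))
    top = (
        sig.sort_values(["p_value", "ai", "_coord"], ascending=[True, False, True])
        .groupby("region_id", as_index=False)
        .first()
        .drop(columns="_coord")
    )
    return sig.drop(columns="_coord"), top


def _variant_coord(vid: str) -> int:
    try:
        return int(vid.split(":")[1])
    except (IndexError, ValueError):
        return 0


def concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    fdr_threshold: float = 0.01,
    min_ai: float = 0.1,
    component: str = "full",
) -> dict:
    """Direction agreement between two conditions on shared variants.

    Concordant = both reference-biased or both alternative-biased, among
    variants significant in both tables.  Also reports the Spearman
    correlation of signed imbalance (ref_bias - 0.5) over all shared variants.
    """
    a = results_a[results_a["component"] == component].set_index("variant_id")
    b = results_b[results_b["component"] == component].set_index("variant_id")
    shared = a.index.intersection(b.index)
    out = {"n_shared": int(len(shared)), "concordance": float("nan"),
           "n_significant_both": 0, "spearman": float("nan")}
    if len(shared) == 0:
        return out
    sa, sb = a.loc[shared], b.loc[shared]
    if len(shared) > 2:
        out["spearman"] = float(stats.spearmanr(sa["ref_bias"] - 0.5,
                                                sb["ref_bias"] - 0.5).statistic)
    sig = ((sa["fdr"] < fdr_threshold) & (sa["ai"] > min_ai)
           & (sb["fdr"] < fdr_threshold) & (sb["ai"] > min_ai))
    out["n_significant_both"] = int(sig.sum())
    if sig.sum() > 0:
        same = np.sign(sa.loc[sig, "ref_bias"] - 0.5) == np.sign(sb.loc[sig, "ref_bias"] - 0.5)
        out["concordance"] = float(same.mean())
    return out
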