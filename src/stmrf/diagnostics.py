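"""Model comparison (DIC/WAIC), variance partitioning, RR transforms.

Deviance is -2 times the (unsaturated) Poisson log likelihood; additive
constants cancel in every model comparison on the same data.  DIC follows
the classical definition D-bar + p_D with p_D = D-bar - D(posterior mean);
WAIC is the pointwise predictive criterion -2 (lppd - p_WAIC).  A DIC
difference above 3 between models on the same panel is flagged as a
meaningful preference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .inference import PosteriorSummary, draw_latent
from .panel import PanelData

__all__ = [
    "FitComparison",
    "dic",
    "waic",
    "model_deviance_draws",
    "pointwise_lpd_draws",
    "compute_dic",
    "compute_waic",
    "compare_models",
    "variance_partition",
    "rr_percent_change",
    "rr_percent_label",
]

DIC_SIGNIFICANCE = 3.0


@dataclass
class FitComparison:
    """Comparison table across fits of the same panel."""

    table: pd.DataFrame    # per-model D_bar, p_D, DIC, WAIC, deltas, flag

    @property
    def best(self) -> str:
        return self.table["DIC"].idxmin()


def dic(deviance_samples, deviance_at_mean: float):
    """(D-bar, p_D, DIC) from posterior deviance draws.

    p_D = D-bar - D(eta-hat); DIC = D-bar + p_D.  Warns on negative p_D
    (a sign of a poorly-identified posterior mean).
    """
    dev = np.asarray(deviance_samples, dtype=float)
    if dev.size < 2:
        raise ValueError("need at least 2 deviance evaluations")
    d_bar = float(dev.mean())
    p_d = d_bar - float(deviance_at_mean)
    if p_d < 0:
        warnings.warn(f"negative effective parameter count p_D = {p_d:.3f}",
                      stacklevel=2)
    return d_bar, p_d, d_bar + p_d


def waic(lpd_draws):
    """(lppd, p_WAIC, WAIC) from pointwise log predictive density draws.

    ``lpd_draws`` is (n_draws, n_cells): log p(y_cell | eta_draw).
    """
    lpd = np.asarray(lpd_draws, dtype=float)
    if lpd.ndim != 2 or lpd.shape[0] < 2:
        raise ValueError("need a (n_draws >= 2, n_cells) array of draws")
    n = lpd.shape[0]
    lppd = float(np.sum(logsumexp(lpd, axis=0) - np.log(n)))
    p_waic = float(np.sum(lpd.var(axis=0, ddof=1)))
    return lppd, p_waic, -2.0 * (lppd - p_waic)


def _cell_loglik(O, e, eta):
    """Per-cell Poisson log pmf at mean e*exp(eta) for exposed cells."""
    with np.errstate(over="ignore"):
        lam = e * np.exp(np.clip(eta, -60, 60))
        return O * np.log(np.where(lam > 0, lam, 1.0)) - lam - gammaln(O + 1.0)


def model_deviance_draws(summary: PosteriorSummary, panel: PanelData,
                         n_draws: int = 200, seed: int | None = None):
    """(deviance draws, deviance at posterior-mean eta)."""
    etas, _ = draw_latent(summary, n_draws, seed)
    O = panel.flat(panel.O).astype(float)
    e = panel.flat(panel.e)
    m = panel.mask
    dev = -2.0 * _cell_loglik(O[m], e[m], etas[:, m]).sum(axis=1)
    dev_mean = -2.0 * float(_cell_loglik(O[m], e[m], summary.eta_mean[m]).sum())
    return dev, dev_mean


def pointwise_lpd_draws(summary: PosteriorSummary, panel: PanelData,
                        n_draws: int = 200, seed: int | None = None):
    etas, _ = draw_latent(summary, n_draws, seed)
    O = panel.flat(panel.O).astype(float)
    e = panel.flat(panel.e)
    m = panel.mask
    return _cell_loglik(O[m], e[m], etas[:, m])


def compute_dic(summary: PosteriorSummary, panel: PanelData,
                n_draws: int = 200, seed: int | None = None):
    dev, dev_mean = model_deviance_draws(summary, panel, n_draws, seed)
    return dic(dev, dev_mean)


def compute_waic(summary: PosteriorSummary, panel: PanelData,
                 n_draws: int = 200, seed: int | None = None):
    return waic(pointwise_lpd_draws(summary, panel, n_draws, seed))


def compare_models(fits: dict, panel: PanelData, n_draws: int = 200,
                   seed: int | None = 0) -> FitComparison:
    """DIC/WAIC comparison of named fits of the *same* panel.

    Raises if any fit was produced on different data (hash check).
    Flags models whose DIC exceeds the best by more than 3.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    hashes = {s.data_hash for s in fits.values()}
    if len(hashes) != 1:
        raise ValueError("fits were produced on different panels")
    rows = {}
    for name, s in fits.items():
        d_bar, p_d, d = compute_dic(s, panel, n_draws, seed)
        lppd, p_w, w = compute_waic(s, panel, n_draws, seed)
        rows[name] = {"D_bar": d_bar, "p_D": p_d, "DIC": d,
                      "lppd": lppd, "p_WAIC": p_w, "WAIC": w}
    table = pd.DataFrame(rows).T
    table["delta_DIC"] = table["DIC"] - table["DIC"].min()
    table["delta_WAIC"] = table["WAIC"] - table["WAIC"].min()
    table["significant"] = table["delta_DIC"] > DIC_SIGNIFICANCE
    return FitComparison(table=table)


def variance_partition(summary: PosteriorSummary) -> dict:
    """Share of latent log-risk variability per random-effect family.

    Empirical variances of the posterior-mean effect fields mapped to the
    full area-by-period grid: spatial (ICAR v), heterogeneity (iid u),
    temporal (RW1 trend + iid period effect), interaction (psi).
    Proportions sum to 1; an all-zero fit returns a uniform split with a
    warning.
    """
    model = summary._state["model"]
    S, T = model.panel.S, model.panel.T
    em = summary.effect_means
    fields = {}
    if "v" in em:
        fields["spatial"] = np.tile(em["v"], T)
    if "u" in em:
        fields["heterogeneity"] = np.tile(em["u"], T)
    temporal = np.zeros(S * T)
    got_t = False
    for nm in ("gamma", "phi"):
        if nm in em:
            temporal = temporal + np.repeat(em[nm], S)
            got_t = True
    if got_t:
        fields["temporal"] = temporal
    if "psi" in em:
        fields["interaction"] = em["psi"]

    variances = {k: float(np.var(v)) for k, v in fields.items()}
    total = sum(variances.values())
    if total <= 0:
        warnings.warn("all effect fields are zero; returning uniform shares",
                      stacklevel=2)
        return {k: 1.0 / len(fields) for k in fields}
    return {k: v / total for k, v in variances.items()}


def rr_percent_change(beta: float) -> float:
    """Signed percent change in relative risk per one-unit (1 sd) increase
    of a standardized covariate: 100 (exp(beta) - 1)."""
    return 100.0 * (np.exp(float(beta)) - 1.0)


def rr_percent_label(beta: float) -> str:
    """Report-style integer label, e.g. '34% decrease' for beta = -0.42."""
    pct = rr_percent_change(beta)
    if round(abs(pct)) == 0:
        return "0%"
    direction = "increase" if pct > 0 else "decrease"
    return f"{round(abs(pct)):.0f}% {direction}"
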