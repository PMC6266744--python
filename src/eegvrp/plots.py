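"""Simple diagnostic figures: VRP against age with a linear fit, and the
logistic risk curve over VRP.

Requires matplotlib (optional dependency); figures are returned so
callers can save or show them.
"""

from __future__ import annotations

import numpy as np

from .inference import VRPLogisticScreen, fit_linear


def _require_pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires the optional 'matplotlib' dependency"
        ) from exc
    return plt


def vrp_vs_age(age_days, vrp_values, ax=None):
    """Scatter of session VRP against age with the OLS line."""
    plt = _require_pyplot()
    age = np.asarray(age_days, dtype=float)
    v = np.asarray(vrp_values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(age, v, s=25, alpha=0.8)
    import pandas as pd

    fit = fit_linear(v, pd.DataFrame({"age": age}), outcome_name="vrp")
    grid = np.linspace(age.min(), age.max(), 50)
    ax.plot(grid, fit.params[0] + fit.params[1] * grid, lw=2)
    ax.set_xlabel("age (days, adjusted)")
    ax.set_ylabel("variance of relative power")
    return ax


def logistic_risk_curve(vrp_values, at_risk, ax=None, threshold=0.5):
    """At-risk status against VRP with the fitted logistic probability."""
    plt = _require_pyplot()
    v = np.asarray(vrp_values, dtype=float)
    y = np.asarray(at_risk)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    est = VRPLogisticScreen(threshold=threshold).fit(v, y)
    grid = np.linspace(v.min(), v.max(), 200)
    ax.plot(grid, est.predict_proba(grid)[:, 1], lw=2)
    jitter = (np.random.default_rng(0).uniform(-0.02, 0.02, v.size))
    ax.scatter(v, (y == est.classes_[1]).astype(float) + jitter, s=25, alpha=0.7)
    ax.set_xlabel("variance of relative power")
    ax.set_ylabel("P(at risk)")
    ax.set_ylim(-0.1, 1.1)
    return ax
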