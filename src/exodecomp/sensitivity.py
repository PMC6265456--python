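"""Depletion sensitivity and log2 fold changes.

The sensitivity of an RNA to exosome (RRP40) or NEXT (RBM7) depletion is

    s = (E_KD - E_CTRL) / E_KD,   clamped to [0, 1],

where E_KD and E_CTRL are replicate means of normalized expression in the
depleted and control libraries of one cell state.  s = 0 means no change upon
depletion; s -> 1 means the RNA is detected almost exclusively when the decay
machinery is impaired.  Negative values (lower expression upon depletion) are
set to 0, and 0/0 is defined as 0: absence of signal is no evidence of
stabilization.

Under the generative model of :mod:`exodecomp.simulate` (control mean
proportional to tau*(1-delta), depleted mean to tau*(1-eps*delta)), the
population value of s is delta*(1-eps)/(1-eps*delta), which reduces to delta
for a fully effective depletion (eps = 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = [
    "population_sensitivity",
    "compute_sensitivity",
    "compute_log2fc",
    "state_log2fc",
    "kd_log2fc",
    "group_means",
]


def population_sensitivity(delta, epsilon):
    """Noise-free sensitivity implied by decay fraction ``delta`` and residual
    decay ``epsilon`` (1 = no depletion effect): delta*(1-eps)/(1-eps*delta)."""
    delta = np.asarray(delta, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    return delta * (1.0 - epsilon) / (1.0 - epsilon * delta)


def _values(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def group_means(expr, design: pd.DataFrame, **selector) -> pd.Series:
    """Replicate mean per feature over the design rows matching ``selector``.

    ``selector`` filters on design columns, e.g. ``state="ESC",
    condition="control"``.  Raises if no sample matches.
    """
    values = _values(expr)
    mask = pd.Series(True, index=design.index)
    for col, val in selector.items():
        mask &= design[col] == val
    samples = design.loc[mask, "sample_id"]
    samples = [s for s in samples if s in values.columns]
    if not samples:
        raise ValueError(f"no samples match {selector!r}")
    return values[samples].mean(axis=1)


def compute_sensitivity(
    expr,
    design: pd.DataFrame,
    factor: str,
    state: str,
) -> pd.DataFrame:
    """Per-feature depletion sensitivity for one state and depletion factor.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame
        Normalized expression (replicate columns), typically quantile
        normalized.
    design : DataFrame
        Sample sheet with columns sample_id, state, condition.
    factor : str
        Depletion condition, ``"RRP40_KD"`` or ``"RBM7_KD"``.
    state : str
        Cell state, ``"ESC"`` or ``"EBd3"``.

    Returns
    -------
    DataFrame indexed by feature with columns feature_id, state, factor,
    mean_expr_kd, mean_expr_ctrl, sensitivity (in [0, 1]).
    """
    if factor not in set(design["condition"]):
        raise ValueError(f"unknown depletion factor {factor!r}")
    if state not in set(design["state"]):
        raise ValueError(f"unknown state {state!r}")
    e_kd = group_means(expr, design, state=state, condition=factor)
    e_ctrl = group_means(expr, design, state=state, condition="control")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (e_kd - e_ctrl) / e_kd
    s = s.where(e_kd > 0, 0.0).clip(lower=0.0, upper=1.0)
    return pd.DataFrame(
        {
            "feature_id": e_kd.index,
            "state": state,
            "factor": factor,
            "mean_expr_kd": e_kd.to_numpy(),
            "mean_expr_ctrl": e_ctrl.to_numpy(),
            "sensitivity": s.to_numpy(),
        }
    ).set_index("feature_id", drop=False)


def compute_log2fc(mean_a: pd.Series, mean_b: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """log2((mean_a + pc) / (mean_b + pc)); antisymmetric under group swap."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)


def state_log2fc(
    expr, design: pd.DataFrame, condition: str = "control", pseudocount: float = 1.0
) -> pd.Series:
    """Per-feature log2 fold change EBd3 vs ESC within one condition."""
    a = group_means(expr, design, state="EBd3", condition=condition)
    b = group_means(expr, design, state="ESC", condition=condition)
    return compute_log2fc(a, b, pseudocount)


def kd_log2fc(
    expr,
    design: pd.DataFrame,
    factor: str,
    state: str | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature log2 fold change depleted vs control.

    With ``state=None`` the contrast pools both states (all depleted vs all
    control samples of the assay); in a balanced design the state effects
    cancel, halving the variance of a change whose true value is zero.
    """
    sel_a = {"condition": factor}
    sel_b = {"condition": "control"}
    if state is not None:
        sel_a["state"] = state
        sel_b["state"] = state
    a = group_means(expr, design, **sel_a)
    b = group_means(expr, design, **sel_b)
    return compute_log2fc(a, b, pseudocount)
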