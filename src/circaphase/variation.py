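"""Rhythm reconstruction from inferred phases and two-group variation calls.

After phase inference, each gene's expression can be re-fitted against the
inferred phases (used as the time axis, hours in [0, 24)) with a cosinor
whose period is chosen from a 20-28 h grid by residual sum of squares.
Comparing a control fit against a case fit yields one of six variation
patterns:

  loss of rhythmicity   P_c <= 0.05 and P_d >  0.05
  gain of rhythmicity   P_c >  0.05 and P_d <= 0.05
  period change         both <= 0.05 and |T_c - T_d| > 2 h
  amplitude change / phase shift / base shift
                        both <= 0.05 and |T_c - T_d| < 2 h, assessed by
                        Wald tests on the cosinor coefficients (several
                        labels may co-occur)

|T_c - T_d| exactly 2 h falls in neither gate of the printed rules; such
calls are labeled ``indeterminate_period_boundary`` instead of being forced
into a category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cosinor import CosinorFit, fit_cosinor_grid
from .metrics import PhaseVector
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariationCall",
    "reconstruct_rhythm",
    "classify_variation",
    "test_param_difference",
]

RHYTHM_ALPHA = 0.05
PERIOD_DELTA_H = 2.0
DEFAULT_PERIOD_GRID = tuple(range(20, 29))

LABELS = (
    "loss_of_rhythmicity",
    "gain_of_rhythmicity",
    "period_change",
    "amplitude_change",
    "phase_shift",
    "base_shift",
)


@dataclass
class VariationCall:
    gene_id: str
    labels: list[str]
    fit_control: CosinorFit
    fit_case: CosinorFit
    difference_pvalues: dict[str, float] = field(default_factory=dict)


def reconstruct_rhythm(
    matrix: ExpressionMatrix,
    phases: PhaseVector,
    gene_id: str,
    period_grid=DEFAULT_PERIOD_GRID,
) -> CosinorFit:
    """Cosinor fit of one gene against the inferred phases.

    Phases (hours) serve directly as the time covariate; the candidate
    period only enters the cosine argument.  The best grid period by RSS is
    kept and its zero-amplitude F-test gives the rhythmicity p-value.
    """
    if phases.sample_ids is not None:
        order = [phases.sample_ids.index(s) for s in matrix.sample_ids]
        t = phases.phases_h[order]
    else:
        t = phases.phases_h
    if matrix.n_samples < 6:
        raise ValueError("rhythm reconstruction needs at least 6 samples")
    y = matrix.data.loc[gene_id].to_numpy(dtype=float)
    return fit_cosinor_grid(y, t, periods=period_grid)


def _wald_p(diff: float, var: float) -> float:
    if var <= 0 or not np.isfinite(var):
        raise np.linalg.LinAlgError("singular covariance in Wald test")
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def test_param_difference(
    fit_c: CosinorFit,
    fit_d: CosinorFit,
    param: str,
) -> float:
    """Wald test for a difference in one cosinor parameter between groups.

    Uses each fit's asymptotic covariance of (mesor, beta_cos, beta_sin)
    and the delta method for the derived amplitude/acrophase parameters.
    Acrophase differences are taken on the circle (wrapped to [-pi, pi]).
    """
    def grad_and_value(fit: CosinorFit, which: str):
        b0, bc, bs = fit.beta
        a = np.hypot(bc, bs)
        if which == "mesor":
            return b0, np.array([1.0, 0.0, 0.0])
        if which == "amplitude":
            if a == 0:
                raise np.linalg.LinAlgError("zero amplitude; gradient undefined")
            return a, np.array([0.0, bc / a, bs / a])
        if which == "acrophase":
            if a == 0:
                raise np.linalg.LinAlgError("zero amplitude; angle undefined")
            return np.arctan2(bs, bc), np.array(
                [0.0, -bs / a**2, bc / a**2]
            )
        raise ValueError(f"unknown parameter {which!r}")

    v_c, g_c = grad_and_value(fit_c, param)
    v_d, g_d = grad_and_value(fit_d, param)
    var = float(g_c @ fit_c.cov @ g_c + g_d @ fit_d.cov @ g_d)
    diff = v_d - v_c
    if param == "acrophase":
        diff = np.mod(diff + np.pi, 2.0 * np.pi) - np.pi
    return _wald_p(float(diff), var)


def classify_variation(
    fit_c: CosinorFit,
    fit_d: CosinorFit,
    gene_id: str = "",
    alpha: float = RHYTHM_ALPHA,
    diff_alpha: float = RHYTHM_ALPHA,
) -> VariationCall:
    """Apply the six-pattern rule set to a control/case pair of fits."""
    labels: list[str] = []
    diff_p: dict[str, float] = {}
    pc, pd_ = fit_c.p_value, fit_d.p_value
    if pc <= alpha and pd_ > alpha:
        labels.append("loss_of_rhythmicity")
    elif pc > alpha and pd_ <= alpha:
        labels.append("gain_of_rhythmicity")
    elif pc <= alpha and pd_ <= alpha:
        dT = abs(fit_c.period - fit_d.period)
        if dT > PERIOD_DELTA_H:
            labels.append("period_change")
        elif dT == PERIOD_DELTA_H:
            labels.append("indeterminate_period_boundary")
        else:
            for param, label in (
                ("amplitude", "amplitude_change"),
                ("acrophase", "phase_shift"),
                ("mesor", "base_shift"),
            ):
                try:
                    p = test_param_difference(fit_c, fit_d, param)
                except np.linalg.LinAlgError as exc:
                    logger.warning(
                        "%s: %s test skipped (%s)", gene_id, param, exc
                    )
                    continue
                diff_p[param] = p
                if p <= diff_alpha:
                    labels.append(label)
    return VariationCall(gene_id, labels, fit_c, fit_d, diff_p)
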