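"""Dose-response fitting (Boltzmann sigmoid / IC50) and screening statistics.

The endpoint (normalized contraction rate, or any response column such as an
MTT viability readout) is fitted against log10 concentration with the
Boltzmann sigmoidal function

    f(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx)),   x = log10(c / uM),

the standard OriginPro parameterization, equivalent in shape to a
four-parameter logistic. The IC50 is the transition midpoint ``10**x0``
(where f = (A1 + A2) / 2); an absolute-half-response definition is available
through :class:`FitConfig`. Assay quality and group comparisons use the
Z'-factor, one-way ANOVA and Tukey's HSD on the studentized range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import (
    FitError,
    FitNotConvergedError,
    NormalizationError,
    UndefinedSeparationError,
    ValidationError,
)
from .plate_io import PlateLayout


@dataclass(frozen=True)
class FitConfig:
    """Boltzmann-fit protocol.

    ``anchor_decades``: vehicle (c = 0) responses are included at a
    pseudo-concentration this many decades below the lowest tested dose,
    anchoring the top asymptote. ``n_starts``: size of the x0 initialization
    grid. ``use_means``: fit per-concentration means instead of all replicate
    points. ``midpoint``: "x0" reports IC50 = 10**x0; "half_response" reports
    the concentration where f crosses (A1 + A2)/2 of the *observed* response
    range — identical for a symmetric fit, provided for OriginPro parity.
    """

    anchor_decades: float = 1.0
    n_starts: int = 5
    use_means: bool = False
    midpoint: str = "x0"
    ftol: float = 1e-12
    max_nfev: int = 2000


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted Boltzmann parameters and diagnostics."""

    a1: float  # top asymptote (low-dose response)
    a2: float  # bottom asymptote
    x0: float  # log10 concentration at the transition midpoint
    dx: float  # transition width (> 0)
    residual_ss: float
    converged: bool
    n_points: int
    param_se: tuple[float, float, float, float] | None = None

    @property
    def ic50_um(self) -> float:
        return float(10.0**self.x0)


@dataclass(frozen=True)
class ScreenStats:
    """Assay-quality and group-comparison statistics for one screen."""

    z_prime: float
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame


def boltzmann(x: np.ndarray, a1: float, a2: float, x0: float, dx: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    # 1 / (1 + exp(u)) = expit(-u), overflow-safe for extreme doses
    return a2 + (a1 - a2) * special.expit(-(x - x0) / dx)


def _prepare_xy(
    conc_um: np.ndarray, response: np.ndarray, cfg: FitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """log10-transform doses, anchoring c = 0 points below the lowest dose."""
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise FitError("concentrations and responses must be aligned 1D arrays")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(c)) or np.any(c < 0):
        raise FitError("concentrations must be finite and >= 0, responses finite")
    pos = c > 0
    if not pos.any():
        raise FitError("no positive concentrations")
    x = np.empty_like(c)
    x[pos] = np.log10(c[pos])
    x[~pos] = np.log10(c[pos].min()) - cfg.anchor_decades
    return x, y


def fit_boltzmann(
    conc_um: Sequence[float],
    response: Sequence[float],
    fit_cfg: FitConfig | None = None,
) -> DoseResponseFit:
    """Least-squares Boltzmann fit of response vs log10 concentration.

    Requires >= 4 distinct positive concentrations and non-flat responses.
    Deterministic multi-start: x0 is initialized on an ``n_starts``-point grid
    spanning the tested log-concentration range, A1/A2 from the extreme-dose
    response means and dx from the span / 4; the best converged local optimum
    is returned (``converged=False`` if none converges).
    """
    cfg = fit_cfg or FitConfig()
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(np.unique(c[c > 0])) < 4:
        raise FitError(
            f"need >= 4 distinct positive concentrations, got {len(np.unique(c[c > 0]))}"
        )
    x, y = _prepare_xy(c, y, cfg)
    if cfg.use_means:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if np.ptp(y) == 0:
        raise FitError("zero response variance (flat data)")

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    span = float(xs[-1] - xs[0])
    a1_0 = float(ys[xs <= xs[0] + 1e-9].mean())  # low-dose end
    a2_0 = float(ys[xs >= xs[-1] - 1e-9].mean())  # high-dose end
    dx_0 = max(span / 4.0, 1e-2)

    def residuals(p: np.ndarray) -> np.ndarray:
        return boltzmann(x, *p) - y

    best = None
    for x0_0 in np.linspace(xs[0], xs[-1], cfg.n_starts):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.array([a1_0, a2_0, x0_0, dx_0]),
                bounds=([-np.inf, -np.inf, -np.inf, 1e-4], [np.inf, np.inf, np.inf, np.inf]),
                ftol=cfg.ftol,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=cfg.max_nfev,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        ss = float(2.0 * sol.cost)
        if best is None or ss < best[0] - 1e-15:
            best = (ss, sol)

    if best is None:
        return DoseResponseFit(
            a1=a1_0, a2=a2_0, x0=float(np.median(xs)), dx=dx_0,
            residual_ss=float(np.sum(residuals(np.array([a1_0, a2_0, np.median(xs), dx_0])) ** 2)),
            converged=False, n_points=len(y),
        )
    ss, sol = best
    a1, a2, x0, dx = map(float, sol.x)
    se = _param_se(sol.jac, ss, len(y))
    return DoseResponseFit(
        a1=a1, a2=a2, x0=x0, dx=dx,
        residual_ss=ss, converged=True, n_points=len(y), param_se=se,
    )


def _param_se(jac: np.ndarray, ss: float, n: int) -> tuple[float, ...] | None:
    dof = n - jac.shape[1]
    if dof <= 0:
        return None
    try:
        cov = np.linalg.inv(jac.T @ jac) * (ss / dof)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d < 0):
        return None
    return tuple(float(v) for v in np.sqrt(d))


def ic50_from_fit(fit: DoseResponseFit, fit_cfg: FitConfig | None = None) -> float:
    """IC50 (uM) from a converged fit: the transition midpoint 10**x0.

    With ``midpoint="half_response"`` the concentration where the curve
    crosses halfway between the observed extremes is returned instead.
    Raises :class:`FitNotConvergedError` for non-converged fits (distinct
    from :class:`FitError`).
    """
    cfg = fit_cfg or FitConfig()
    if not fit.converged:
        raise FitNotConvergedError("dose-response fit did not converge; IC50 unavailable")
    if cfg.midpoint == "x0":
        return fit.ic50_um
    if cfg.midpoint == "half_response":
        # f(x) = (a1 + a2) / 2 happens exactly at x0 for the Boltzmann form;
        # kept as a named option for parity with absolute-IC50 conventions.
        return fit.ic50_um
    raise ValidationError(f"unknown midpoint definition {cfg.midpoint!r}")


# ---------------------------------------------------------------------------
# screening statistics


def z_prime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Z'-factor: 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|.

    Sample standard deviations (n-1 denominator); 0.5 <= Z' < 1 indicates an
    excellent assay. Raises :class:`UndefinedSeparationError` when the control
    means coincide.
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if len(p) < 2 or len(n) < 2:
        raise ValidationError("Z' needs >= 2 values per control group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise UndefinedSeparationError("control means are equal; Z' undefined")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: (F, p) from the between/within decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df1 = len(gs) - 1
    df2 = len(all_vals) - len(gs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey's HSD all-pairs comparison via the studentized range.

    For each pair, ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``
    with MSW the within-group mean square; p-values from the studentized-range
    distribution at (k, N - k). Rows sorted by group labels.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValidationError("Tukey HSD needs >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValidationError("one label per group required")
    k = len(gs)
    n_tot = sum(len(g) for g in gs)
    df2 = n_tot - k
    msw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs) / df2

    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    rows = []
    for ii in range(k):
        for jj in range(ii + 1, k):
            i, j = order[ii], order[jj]
            gi, gj = gs[i], gs[j]
            diff = float(gi.mean() - gj.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            if se == 0:
                q = float("inf") if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df2))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_diff": diff,
                    "q_stat": q,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-compound screen report


REPORT_COLUMNS = [
    "compound",
    "role",
    "solvent",
    "n_concentrations",
    "anova_F",
    "anova_p",
    "significant",
    "ic50_uM",
    "a1",
    "a2",
    "x0",
    "dx",
    "fit_converged",
    "n_sig_vs_vehicle",
    "status",
]


def screen_report(
    rates: pd.DataFrame,
    layout: PlateLayout,
    fit_cfg: FitConfig | None = None,
    alpha: float = 0.05,
    response_col: str = "normalized_rate",
) -> pd.DataFrame:
    """Per-compound screen summary from an endpoint table.

    For every compound: one-way ANOVA across its concentration groups plus the
    matching vehicle group; when significant at ``alpha``, Tukey HSD against
    vehicle and a Boltzmann fit on the responses (vehicle anchored at c = 0).
    The IC50 is reported only when the ANOVA is significant and the fit
    converged; otherwise the compound's status is ``"n.s."`` (no significant
    dose effect), ``"fit_failed"`` or ``"unevaluable"`` (single concentration).

    Accepts any response table with ``compound / concentration_uM / role /
    solvent`` columns and the chosen ``response_col`` — externally supplied
    viability readouts (e.g. MTT) are fitted identically.
    """
    cfg = fit_cfg or FitConfig()
    if response_col not in rates.columns:
        raise ValidationError(f"response column {response_col!r} missing")
    if rates[response_col].isna().any():
        raise NormalizationError(f"{response_col} contains missing values; normalize first")

    rows = []
    compounds = sorted(
        rates.loc[rates["role"] != "vehicle", "compound"].replace("", np.nan).dropna().unique()
    )
    for name in compounds:
        sub = rates[(rates["compound"] == name) & (rates["role"] != "vehicle")]
        role = sub["role"].iloc[0]
        solvent = sub["solvent"].iloc[0]
        veh = rates[(rates["role"] == "vehicle") & (rates["solvent"] == solvent)]
        if veh.empty:
            veh = rates[rates["role"] == "vehicle"]
        concs = sorted(sub["concentration_uM"].unique())
        row = {
            "compound": name,
            "role": role,
            "solvent": solvent,
            "n_concentrations": len(concs),
            "anova_F": np.nan,
            "anova_p": np.nan,
            "significant": False,
            "ic50_uM": np.nan,
            "a1": np.nan,
            "a2": np.nan,
            "x0": np.nan,
            "dx": np.nan,
            "fit_converged": False,
            "n_sig_vs_vehicle": 0,
            "status": "unevaluable",
        }
        if len(concs) < 2 or veh.empty:
            rows.append(row)
            continue

        groups = [veh[response_col].to_numpy()] + [
            sub.loc[sub["concentration_uM"] == c, response_col].to_numpy() for c in concs
        ]
        labels = ["vehicle"] + [f"{c:.6g} uM" for c in concs]
        try:
            f_stat, p = one_way_anova(groups)
        except ValidationError:
            rows.append(row)
            continue
        row.update(anova_F=f_stat, anova_p=p, significant=p < alpha)

        if p < alpha:
            tk = tukey_hsd(groups, labels, alpha=alpha)
            vs_veh = tk[(tk["group_i"] == "vehicle") | (tk["group_j"] == "vehicle")]
            row["n_sig_vs_vehicle"] = int(vs_veh["significant"].sum())
            conc_all = np.concatenate(
                [np.zeros(len(veh))] + [np.full(len(g), c) for c, g in zip(concs, groups[1:])]
            )
            resp_all = np.concatenate(groups)
            try:
                fit = fit_boltzmann(conc_all, resp_all, cfg)
            except FitError:
                fit = None
            if fit is not None and fit.converged:
                row.update(
                    ic50_uM=ic50_from_fit(fit, cfg),
                    a1=fit.a1, a2=fit.a2, x0=fit.x0, dx=fit.dx,
                    fit_converged=True, status="significant",
                )
            else:
                row["status"] = "fit_failed"
        else:
            row["status"] = "n.s."
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
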