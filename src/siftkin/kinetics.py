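"""Steady-state saturation kinetics: Hill fits, fold changes and accounting.

The central object is :class:`HillModel`, a statsmodels-style model built
from assay data. The Hill equation

.. math::

    v(S) = \\frac{V_{max} \\, S^{h}}{K^{h} + S^{h}}

describes initial velocity *v* as a function of substrate concentration *S*
(µM) with maximal velocity ``Vmax``, half-saturation constant ``Km`` (µM)
and Hill coefficient ``h``; ``h = 1`` reduces to Michaelis–Menten.
``fit()`` returns a :class:`HillFitResults` carrying the estimates, their
standard errors, the turnover number ``kcat = Vmax / [E]0`` and the
specificity constant ``kcat/Km``, plus a ``summary()`` table.

The fit is nonlinear least squares in log-parameters, which enforces
positivity; standard errors come from the Jacobian at the optimum via the
delta method. Replicates are fitted pooled (not averaged) so the residual
scatter feeds the standard errors.

Module-level helpers cover the surrounding accounting: mutant-vs-wild-type
fold changes, relative-activity tables normalised to a 100% reference
condition, and purification tables (specific activity, yield %, fold).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AssayPoint",
    "HillParams",
    "HillModel",
    "HillFitResults",
    "hill_velocity",
    "fit_hill",
    "fold_change",
    "relative_activity",
    "purification_summary",
    "read_assay_table",
]


@dataclass(frozen=True)
class AssayPoint:
    """One initial-velocity measurement at a substrate concentration (µM)."""

    substrate_conc: float
    velocity: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValueError("substrate concentration must be >= 0")
        if not math.isfinite(self.velocity):
            raise ValueError("velocity must be finite")


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: Vmax (velocity units), Km (µM), h."""

    Vmax: float
    Km: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.Vmax <= 0 or self.Km <= 0 or self.h <= 0:
            raise ValueError("Vmax, Km and h must all be positive")


def hill_velocity(params: HillParams, S) -> np.ndarray | float:
    """Hill-equation velocity v = Vmax·S^h / (Km^h + S^h); v(0) = 0.

    Strictly increasing in S for S > 0 and bounded above by Vmax.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    with np.errstate(divide="ignore"):
        Sh = np.power(S_arr, params.h)
    v = params.Vmax * Sh / (params.Km ** params.h + Sh)
    return float(v) if np.isscalar(S) else v


def _as_points(data) -> list[AssayPoint]:
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        conc_col = cols.get("substrate_conc_um") or cols.get("substrate_conc")
        vel_col = cols.get("velocity")
        if conc_col is None or vel_col is None:
            raise ValueError(
                "DataFrame must have substrate_conc_uM and velocity columns")
        rep_col = cols.get("replicate")
        reps = data[rep_col] if rep_col else [0] * len(data)
        return [
            AssayPoint(float(s), float(v), int(r))
            for s, v, r in zip(data[conc_col], data[vel_col], reps)
        ]
    return [
        p if isinstance(p, AssayPoint) else AssayPoint(*p)
        for p in data
    ]


class HillModel:
    """Hill-equation model of pooled saturation-assay data.

    Parameters
    ----------
    data : sequence of AssayPoint (or (conc, velocity[, replicate]) tuples)
        Pooled replicate measurements.
    enzyme_conc : float
        Total enzyme concentration [E]0 in µM, used to convert Vmax into the
        turnover number kcat = Vmax / [E]0. Required: docking/assay files do
        not carry it.
    """

    def __init__(self, data, enzyme_conc: float):
        self.points = _as_points(data)
        if enzyme_conc is None or enzyme_conc <= 0:
            raise ValueError("enzyme_conc (µM) must be positive")
        self.enzyme_conc = float(enzyme_conc)
        self.S = np.array([p.substrate_conc for p in self.points])
        self.v = np.array([p.velocity for p in self.points])
        if len(np.unique(self.S[self.S > 0])) < 4:
            raise ValueError(
                "need at least 4 distinct non-zero substrate concentrations")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme_conc: float) -> "HillModel":
        return cls(df, enzyme_conc)

    # -- fitting -----------------------------------------------------------

    def fit(self, fix_h: float | None = None, max_iter: int = 500,
            xtol: float = 1e-12) -> "HillFitResults":
        """Nonlinear least squares in log(Vmax), log(Km)[, log(h)].

        ``fix_h=1`` pins the Hill coefficient, reducing the model to
        Michaelis–Menten. A degenerate dataset (no saturation signal, e.g.
        all velocities equal) yields ``converged=False`` with NaN errors
        rather than silent estimates.
        """
        S, v = self.S, self.v
        v_range = float(np.max(v) - np.min(v))
        degenerate = v_range <= 1e-12 * max(1.0, float(np.max(np.abs(v))))

        Vmax0 = max(float(np.max(v)), 1e-12)
        half = Vmax0 / 2.0
        pos = S > 0
        Km0 = float(S[pos][np.argmin(np.abs(v[pos] - half))]) if pos.any() else 1.0
        Km0 = max(Km0, 1e-6)
        h0 = 1.0

        free_h = fix_h is None

        def unpack(theta: np.ndarray) -> HillParams:
            Vmax = math.exp(theta[0])
            Km = math.exp(theta[1])
            h = math.exp(theta[2]) if free_h else float(fix_h)
            return HillParams(Vmax, Km, h)

        def residuals(theta: np.ndarray) -> np.ndarray:
            return hill_velocity(unpack(theta), S) - v

        theta0 = np.log([Vmax0, Km0] + ([h0] if free_h else []))
        if degenerate:
            return HillFitResults(
                model=self, params=HillParams(Vmax0, Km0, h0),
                bse={}, cov=None, rss=float(np.sum((v - np.mean(v)) ** 2)),
                converged=False, fixed_h=fix_h)

        sol = least_squares(residuals, theta0, method="lm",
                            xtol=xtol, ftol=1e-12, gtol=1e-12,
                            max_nfev=max_iter * (len(theta0) + 1))
        params = unpack(sol.x)
        rss = float(np.sum(sol.fun ** 2))
        n, p = len(v), len(sol.x)
        cov = None
        bse_log = np.full(p, np.nan)
        if n > p:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.inv(jtj) * rss / (n - p)
                bse_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            except np.linalg.LinAlgError:
                cov = None
        # delta method: SE(x) = x * SE(log x)
        names = ["Vmax", "Km"] + (["h"] if free_h else [])
        values = [params.Vmax, params.Km] + ([params.h] if free_h else [])
        bse = {nm: val * se for nm, val, se in zip(names, values, bse_log)}
        return HillFitResults(
            model=self, params=params, bse=bse, cov=cov, rss=rss,
            converged=bool(sol.success), fixed_h=fix_h)


@dataclass
class HillFitResults:
    """Fitted Hill model: estimates, standard errors and derived constants."""

    model: HillModel
    params: HillParams
    bse: dict
    cov: np.ndarray | None
    rss: float
    converged: bool
    fixed_h: float | None = None

    # -- derived quantities ------------------------------------------------

    @property
    def kcat(self) -> float:
        """Turnover number Vmax / [E]0 (min⁻¹ when velocity is per minute)."""
        return self.params.Vmax / self.model.enzyme_conc

    @property
    def kcat_over_Km(self) -> float:
        """Specificity constant kcat / Km (min⁻¹ µM⁻¹)."""
        return self.kcat / self.params.Km

    @property
    def kcat_se(self) -> float:
        return self.bse.get("Vmax", float("nan")) / self.model.enzyme_conc

    @property
    def kcat_over_Km_se(self) -> float:
        """Delta-method SE of kcat/Km from the log-parameter covariance."""
        if self.cov is None:
            return float("nan")
        # log(kcat/Km) = log Vmax - log [E]0 - log Km
        var = self.cov[0, 0] + self.cov[1, 1] - 2 * self.cov[0, 1]
        return self.kcat_over_Km * math.sqrt(max(var, 0.0))

    def predict(self, S) -> np.ndarray | float:
        return hill_velocity(self.params, S)

    def to_dict(self) -> dict:
        return {
            "Vmax": self.params.Vmax,
            "Km": self.params.Km,
            "h": self.params.h,
            "kcat": self.kcat,
            "kcat_over_Km": self.kcat_over_Km,
            "se": dict(self.bse),
            "kcat_se": self.kcat_se,
            "kcat_over_Km_se": self.kcat_over_Km_se,
            "rss": self.rss,
            "converged": self.converged,
            "enzyme_conc": self.model.enzyme_conc,
            "n_points": len(self.model.points),
            "fixed_h": self.fixed_h,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Hill-equation fit",
            "=" * 46,
            f"observations: {d['n_points']}   enzyme conc: "
            f"{d['enzyme_conc']:g} µM   converged: {d['converged']}",
            f"RSS: {d['rss']:.6g}",
            "-" * 46,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
        ]
        rows = [("Vmax", self.params.Vmax, self.bse.get("Vmax")),
                ("Km (µM)", self.params.Km, self.bse.get("Km"))]
        if self.fixed_h is None:
            rows.append(("h", self.params.h, self.bse.get("h")))
        else:
            rows.append(("h (fixed)", self.params.h, None))
        rows += [("kcat (min⁻¹)", self.kcat, self.kcat_se),
                 ("kcat/Km", self.kcat_over_Km, self.kcat_over_Km_se)]
        for name, val, se in rows:
            se_s = f"{se:>14.4g}" if se is not None and math.isfinite(se) \
                else f"{'—':>14}"
            lines.append(f"{name:<14}{val:>14.4g}{se_s}")
        return "\n".join(lines)


def fit_hill(data, enzyme_conc: float, fix_h: float | None = None
             ) -> HillFitResults:
    """Functional wrapper: ``HillModel(data, enzyme_conc).fit(fix_h=...)``."""
    return HillModel(data, enzyme_conc).fit(fix_h=fix_h)


# --------------------------------------------------------------------------
# fold changes and accounting tables
# --------------------------------------------------------------------------

def fold_change(a: HillFitResults, b: HillFitResults) -> dict:
    """Elementwise kinetic-parameter ratios a/b (e.g. mutant over wild type)."""
    if not (a.converged and b.converged):
        raise ValueError("fold change requires two converged fits")
    for denom in (b.kcat, b.params.Km, b.kcat_over_Km):
        if denom == 0:
            raise ZeroDivisionError("zero denominator in fold change")
    return {
        "kcat": a.kcat / b.kcat,
        "Km": a.params.Km / b.params.Km,
        "kcat_over_Km": a.kcat_over_Km / b.kcat_over_Km,
    }


def relative_activity(
    table: Mapping[str, float] | pd.DataFrame,
    reference: str,
) -> pd.DataFrame:
    """Normalise raw activities to a reference condition defined as 100%.

    ``table`` maps condition label → raw activity; NaN (or the literal
    "ND", for conditions where the enzyme precipitated) propagates as ND.
    """
    if isinstance(table, pd.DataFrame):
        if "label" in table.columns and "activity" in table.columns:
            series = table.set_index("label")["activity"]
        else:
            series = table.iloc[:, -1]
            series.index = table.iloc[:, 0]
    else:
        series = pd.Series(table, dtype=object)
    series = series.map(
        lambda x: np.nan if isinstance(x, str) and x.strip().upper() == "ND"
        else float(x))
    if reference not in series.index:
        raise KeyError(f"reference condition {reference!r} not in table")
    ref = series[reference]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("reference activity must be finite and non-zero")
    rel = 100.0 * series / ref
    out = pd.DataFrame({"raw_activity": series, "relative_pct": rel})
    out.index.name = "condition"
    return out


def purification_summary(
    steps: Sequence[tuple],
    yield_reference: str | None = None,
    fold_reference: str | float | None = None,
) -> pd.DataFrame:
    """Purification accounting: specific activity, yield % and fold per step.

    ``steps`` are ``(label, total_protein_mg, total_activity_U)`` rows;
    activity may be NaN for steps where it was not measured (e.g. a crude
    extract assayed only after heat treatment). Per step:

    * specific activity = total activity / total protein (U/mg);
    * yield % = 100 × total activity / total activity of the
      ``yield_reference`` step (default: the first step with measured
      activity);
    * fold = specific activity / baseline, where the baseline is either the
      specific activity of the ``fold_reference`` step (by label) or an
      explicit specific-activity value (float) when the true starting
      material's activity could not be assayed directly.
    """
    rows = []
    for label, protein, activity in steps:
        if protein is not None and not (isinstance(protein, float) and np.isnan(protein)):
            if protein <= 0:
                raise ValueError(f"step {label!r}: total protein must be > 0")
        rows.append((label, float(protein), np.nan if activity is None else float(activity)))
    df = pd.DataFrame(rows, columns=["step", "total_protein_mg", "total_activity_U"])
    df["specific_activity"] = df["total_activity_U"] / df["total_protein_mg"]

    measured = df[df["total_activity_U"].notna()]
    if measured.empty:
        raise ValueError("no step has a measured total activity")
    if yield_reference is None:
        yield_ref_activity = float(measured.iloc[0]["total_activity_U"])
    else:
        sel = df[df["step"] == yield_reference]
        if sel.empty or not np.isfinite(sel.iloc[0]["total_activity_U"]):
            raise ValueError(f"yield reference {yield_reference!r} has no activity")
        yield_ref_activity = float(sel.iloc[0]["total_activity_U"])
    df["yield_pct"] = 100.0 * df["total_activity_U"] / yield_ref_activity

    if fold_reference is None:
        baseline = float(measured.iloc[0]["specific_activity"])
    elif isinstance(fold_reference, str):
        sel = df[df["step"] == fold_reference]
        if sel.empty or not np.isfinite(sel.iloc[0]["specific_activity"]):
            raise ValueError(f"fold reference {fold_reference!r} has no specific activity")
        baseline = float(sel.iloc[0]["specific_activity"])
    else:
        baseline = float(fold_reference)
    if baseline <= 0:
        raise ValueError("fold baseline must be positive")
    df["fold"] = df["specific_activity"] / baseline
    return df.set_index("step")


# --------------------------------------------------------------------------
# delimited-text input
# --------------------------------------------------------------------------

def read_assay_table(path_or_buf) -> pd.DataFrame:
    """Read a saturation-assay table with columns substrate_conc_uM, velocity
    and optional replicate (comma/tab/whitespace delimited, header required).
    """
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "substrate_conc_um" not in cols or "velocity" not in cols:
        raise ValueError(
            "assay table needs a header with substrate_conc_uM and velocity")
    out = pd.DataFrame({
        "substrate_conc_uM": df[cols["substrate_conc_um"]].astype(float),
        "velocity": df[cols["velocity"]].astype(float),
    })
    out["replicate"] = (df[cols["replicate"]].astype(int)
                        if "replicate" in cols else 0)
    if (out["substrate_conc_uM"] < 0).any():
        raise ValueError("negative substrate concentrations in assay table")
    return out
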