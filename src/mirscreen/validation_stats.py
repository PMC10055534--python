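"""Validation-arm statistics: 4PL dose-response fits and delta-delta-Ct qPCR.

Dose-response curves follow the four-parameter logistic (the "sigmoidal,
4 parameters" convention of standard curve-fitting software)::

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x)^hill)

with ``bottom`` the response at vanishing dose (fold-change units, ~1 for
an inactive baseline), ``top`` the plateau (the maximal fold change),
``ec50`` the dose at half-maximal response and ``hill > 0`` the slope.
Fitting is nonlinear least squares in log10-dose space, each replicate
entering as an individual point.  ``ECf`` generalizes EC50 to any fraction
f of the dynamic range:  x_f = ec50 * (f / (1 - f))^(1 / hill); "EC100",
which strictly does not exist for a logistic, is reported as x_0.99 by a
declared convention.

Relative qPCR quantification uses the delta-delta-Ct method with an
amplification efficiency fixed at 2: dCt = Ct_target - mean(reference
Cts) (the arithmetic mean of Cts corresponds to the geometric mean of
reference expression), ddCt = dCt - mean(dCt of control samples), fold =
2^(-ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FourParamLogistic",
    "DoseResponseFit",
    "fit_4pl",
    "ec_fraction",
    "DDCtResult",
    "delta_delta_ct",
]


def four_pl(x, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the four-parameter logistic at dose(s) ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


@dataclass
class DoseResponseFit:
    """Results of a 4PL fit: estimates, uncertainties and derived quantities.

    ``max_fold_change`` is the fitted plateau (``top``).  ``extrapolated``
    flags an EC50 outside [min dose / 10, max dose * 10], i.e. effectively
    unconstrained by the tested dose range.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    bse: dict[str, float]
    residual_sd: float
    converged: bool
    extrapolated: bool
    n_obs: int
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> dict[str, float]:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "ec50": self.ec50,
            "hill": self.hill,
        }

    @property
    def max_fold_change(self) -> float:
        return self.top

    def predict(self, doses) -> np.ndarray:
        return four_pl(doses, self.bottom, self.top, self.ec50, self.hill)

    def ec_fraction(self, f: float) -> float:
        """Dose producing fraction ``f`` of the dynamic range (EC50 at 0.5)."""
        if not 0.0 < f < 1.0:
            raise ValueError(f"f must be in (0, 1), got {f}")
        return float(self.ec50 * (f / (1.0 - f)) ** (1.0 / self.hill))

    @property
    def ec100(self) -> float:
        """'EC100' by the x_0.99 convention (the curve has no true maximum)."""
        return self.ec_fraction(0.99)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 45,
            f"  observations: {self.n_obs}",
            f"  converged:    {self.converged}",
            "",
            f"  {'parameter':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:<10}{value:>14.6g}{se:>14.3g}")
        lines += [
            "",
            f"  max fold change (top): {self.top:.4g}",
            f"  EC50: {self.ec50:.4g}" + ("  [extrapolated]" if self.extrapolated else ""),
            f"  EC90: {self.ec_fraction(0.9):.4g}    EC99: {self.ec_fraction(0.99):.4g}",
            f"  residual SD: {self.residual_sd:.4g}",
        ]
        return "\n".join(lines)


class FourParamLogistic:
    """4PL dose-response model for replicate fold-change measurements.

    Parameters
    ----------
    doses : sequence of positive concentrations (any consistent unit); at
        least 4 distinct values are required to identify 4 parameters.
    responses : positive responses, one per dose entry (replicates are
        individual points, not dose means).

    ``fit()`` returns a :class:`DoseResponseFit`.  The fit is invariant to
    replicate order, and rescaling the dose unit rescales ec50 by the same
    factor.
    """

    def __init__(self, doses: Sequence[float], responses: Sequence[float]):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(responses <= 0):
            raise ValueError("responses must be strictly positive")
        if len(np.unique(doses)) < 4:
            raise ValueError("need >= 4 distinct doses to fit 4 parameters")
        if np.allclose(responses, responses[0]):
            raise ValueError("all responses equal; no dynamic range to fit")
        self.doses = doses
        self.responses = responses

    @staticmethod
    def _model_log(logx, bottom, top, log_ec50, hill):
        # 4PL parameterized on log10 dose; numerically safer than dose ratios
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))

    def fit(self, hill_bounds: tuple[float, float] = (0.1, 10.0)) -> DoseResponseFit:
        logx = np.log10(self.doses)
        y = self.responses
        means = pd.Series(y).groupby(pd.Series(self.doses)).mean()
        b0, t0 = float(means.min()), float(means.max())
        b0 = max(b0, 1e-9)
        t0 = max(t0, b0 * (1 + 1e-6))

        def residuals(theta):
            bottom, top, log_ec50, hill = theta
            return self._model_log(logx, bottom, top, log_ec50, hill) - y

        # grid-search the EC50 start over the observed doses
        best_start, best_sse = None, np.inf
        for le in np.unique(logx):
            sse = float(np.sum(residuals((b0, t0, le, 1.0)) ** 2))
            if sse < best_sse:
                best_sse, best_start = sse, le
        lower = [1e-9, 1e-9, logx.min() - 3, hill_bounds[0]]
        upper = [np.inf, np.inf, logx.max() + 3, hill_bounds[1]]
        result = least_squares(
            residuals,
            x0=[b0, t0, best_start, 1.0],
            bounds=(lower, upper),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=5000,
        )
        converged = bool(result.success)
        if not converged:
            warnings.warn(
                "4PL fit did not converge; parameters reported as-is",
                stacklevel=2,
            )
        bottom, top, log_ec50, hill = result.x
        ec50 = 10.0 ** log_ec50
        dof = max(len(y) - 4, 1)
        residual_sd = float(np.sqrt(np.sum(result.fun**2) / dof))
        # covariance from the Jacobian at the solution (Gauss-Newton approx.)
        bse = {k: float("nan") for k in ("bottom", "top", "ec50", "hill")}
        try:
            JTJ = result.jac.T @ result.jac
            cov = np.linalg.inv(JTJ) * residual_sd**2
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            bse = {
                "bottom": float(se[0]),
                "top": float(se[1]),
                # delta method: ec50 = 10^log_ec50
                "ec50": float(np.log(10) * ec50 * se[2]),
                "hill": float(se[3]),
            }
        except np.linalg.LinAlgError:
            pass
        extrapolated = not (
            self.doses.min() / 10.0 <= ec50 <= self.doses.max() * 10.0
        )
        return DoseResponseFit(
            bottom=float(bottom),
            top=float(top),
            ec50=float(ec50),
            hill=float(hill),
            bse=bse,
            residual_sd=residual_sd,
            converged=converged,
            extrapolated=extrapolated,
            n_obs=len(y),
            doses=self.doses,
            responses=y,
        )


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> DoseResponseFit:
    """Fit the 4PL model; convenience wrapper over :class:`FourParamLogistic`."""
    return FourParamLogistic(doses, responses).fit()


def ec_fraction(fit: DoseResponseFit, f: float) -> float:
    """Dose giving fraction ``f`` of the fitted dynamic range."""
    return fit.ec_fraction(f)


# ---------------------------------------------------------------------------
# delta-delta Ct
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("sample", "condition", "gene", "role", "ct")


@dataclass
class DDCtResult:
    """Per-sample relative expression and treated-vs-control fold changes."""

    per_sample: pd.DataFrame  # sample, condition, gene, dct, rel_expr, ddct, fold
    fold_changes: pd.Series  # per target gene: treated-vs-control group fold
    reference_genes: list[str]
    dropped_samples: list[str]

    def summary(self) -> str:
        lines = [
            "delta-delta-Ct quantification",
            "=" * 45,
            f"  reference genes: {', '.join(self.reference_genes)}",
            f"  samples dropped (missing reference): {len(self.dropped_samples)}",
            "",
            "  treated / control fold change (2^-ddCt):",
        ]
        for gene, fold in self.fold_changes.items():
            lines.append(f"    {gene:<20}{fold:>10.4g}")
        return "\n".join(lines)


def delta_delta_ct(table: pd.DataFrame) -> DDCtResult:
    """Relative qPCR quantification by the delta-delta-Ct method.

    ``table`` is long-format with columns ``sample, condition, gene, role,
    ct`` where role is ``target`` or ``reference`` and condition is
    ``treated`` or ``control``.  Reference Cts are combined by arithmetic
    mean (the geometric mean of reference expression at efficiency 2).
    Samples missing any reference gene are dropped with a warning.  The
    group fold change is 2^(-mean ddCt) over treated samples; by
    construction the control group's fold against itself is exactly 1.
    """
    df = table.copy()
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns {missing}")
    df["ct"] = df["ct"].astype(float)
    if ((df["ct"] <= 0) | (df["ct"] >= 50)).any():
        bad = df.loc[(df["ct"] <= 0) | (df["ct"] >= 50)]
        raise ValueError(f"Ct values outside (0, 50): {bad['ct'].tolist()}")
    bad_cond = set(df["condition"]) - {"treated", "control"}
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    if "control" not in set(df["condition"]):
        raise ValueError("no control samples present")
    references = sorted(df.loc[df["role"] == "reference", "gene"].unique())
    if not references:
        raise ValueError("at least one reference gene is required")
    targets = sorted(df.loc[df["role"] == "target", "gene"].unique())

    ref = df[df["role"] == "reference"].pivot_table(
        index="sample", columns="gene", values="ct"
    )
    complete = ref.dropna(how="any")
    dropped = sorted(set(ref.index) - set(complete.index))
    # samples with no reference rows at all are also unusable
    all_samples = set(df["sample"])
    dropped += sorted(all_samples - set(ref.index))
    if dropped:
        warnings.warn(
            f"samples dropped for missing reference genes: {dropped}",
            stacklevel=2,
        )
    ref_mean = complete.mean(axis=1)

    tgt = df[df["role"] == "target"]
    rows = []
    for gene in targets:
        sub = tgt[tgt["gene"] == gene]
        sub = sub[sub["sample"].isin(ref_mean.index)]
        dct = sub.groupby(["sample", "condition"])["ct"].mean() - ref_mean
        dct = dct.dropna()
        frame = dct.reset_index().rename(columns={0: "dct", "ct": "dct"})
        frame.columns = ["sample", "condition", "dct"]
        control_mean = frame.loc[frame["condition"] == "control", "dct"].mean()
        frame["gene"] = gene
        frame["rel_expr"] = 2.0 ** (-frame["dct"])
        frame["ddct"] = frame["dct"] - control_mean
        frame["fold"] = 2.0 ** (-frame["ddct"])
        rows.append(frame)
    per_sample = pd.concat(rows, ignore_index=True)[
        ["sample", "condition", "gene", "dct", "rel_expr", "ddct", "fold"]
    ]
    folds = {}
    for gene in targets:
        sub = per_sample[per_sample["gene"] == gene]
        group = "treated" if (sub["condition"] == "treated").any() else "control"
        folds[gene] = float(
            2.0 ** (-sub.loc[sub["condition"] == group, "ddct"].mean())
        )
    fold_changes = pd.Series(folds, name="fold_change")
    return DDCtResult(per_sample, fold_changes, references, sorted(set(dropped)))
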