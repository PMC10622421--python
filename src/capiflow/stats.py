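"""Statistical layer: transforms, mixed models, marginal means, rmcorr.

Speed and diameter measurements are clustered (many vessels per rat, and
for diameters many measurements per vessel type per rat), so plain
regression would treat non-independent observations as independent.
The analyses here follow the standard mixed-model workflow for such
designs:

* responses are transformed to meet residual-normality assumptions —
  log for speeds, Box-Cox with λ = −0.3 for diameters;
* a linear mixed model is fitted by REML with layer and vessel type as
  fixed effects and rat (or vessel type nested in rat) as random
  effects;
* estimated marginal means (EMMs) per layer are unweighted averages of
  the model's vessel-type cell predictions on the transformed scale,
  with delta-method standard errors, back-transformed for reporting;
* the superficial-vs-deep layer comparison is one-tailed (SL > DL) on
  the transformed scale;
* the association between vessel diameter and speed is summarised by the
  repeated-measures correlation r_rm, the common within-subject
  correlation from a shared-slope, subject-intercept model.

The numerical engine for the mixed models is statsmodels' ``MixedLM``;
the model structure, transforms, EMM weighting and rmcorr statistic are
defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .core_io import logger

Transform = str | tuple[str, float]  # "log" or ("boxcox", lambda)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def boxcox(y, lmbda: float):
    """Box-Cox transform (y^λ − 1)/λ; natural log at λ = 0.

    Strictly increasing in y for every λ, hence order-preserving and
    invertible; defined for positive y only.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if abs(lmbda) < 1e-300:  # includes 0 and subnormals, where λ·ln y underflows
        out = np.log(arr)
    else:
        # expm1 avoids catastrophic cancellation for small |lambda|
        out = np.expm1(lmbda * np.log(arr)) / lmbda
    return out if arr.ndim else float(out)


def inv_boxcox(t, lmbda: float):
    """Exact inverse of :func:`boxcox`."""
    arr = np.asarray(t, dtype=float)
    if abs(lmbda) < 1e-300:
        out = np.exp(arr)
    else:
        if np.any(lmbda * arr <= -1.0):
            raise ValueError("value outside the range of the Box-Cox transform")
        out = np.exp(np.log1p(lmbda * arr) / lmbda)
    return out if arr.ndim else float(out)


def apply_transform(y, transform: Transform):
    if transform == "log":
        arr = np.asarray(y, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("log transform requires positive values")
        return np.log(arr) if arr.ndim else float(np.log(arr))
    if isinstance(transform, tuple) and transform[0] == "boxcox":
        return boxcox(y, transform[1])
    raise ValueError(f"unknown transform {transform!r}")


def invert_transform(t, transform: Transform):
    if transform == "log":
        arr = np.asarray(t, dtype=float)
        return np.exp(arr) if arr.ndim else float(np.exp(arr))
    if isinstance(transform, tuple) and transform[0] == "boxcox":
        return inv_boxcox(t, transform[1])
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# Model specification and fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Structure of one mixed-model analysis.

    ``fixed`` lists the fixed-effect terms (patsy syntax fragments);
    ``random`` is "rat" (random intercept per rat) or "vessel_in_rat"
    (vessel type nested in rat).  Default matches the speed analysis:
    transformed response ~ layer + vessel type, random intercept by rat.
    """

    response: str = "value"
    transform: Transform = "log"
    fixed: tuple[str, ...] = ("C(layer)", "C(vessel_type)")
    random: str = "rat"

    def formula(self) -> str:
        return "y_t ~ " + " + ".join(self.fixed)


SPEED_MODEL = ModelSpec(transform="log")
DIAMETER_MODEL = ModelSpec(
    transform=("boxcox", -0.3),
    fixed=("C(method)", "C(layer)", "C(vessel_type)"),
    random="vessel_in_rat",
)


@dataclass
class FittedModel:
    """A REML mixed-model fit plus everything needed for marginal means."""

    result: object  # statsmodels MixedLMResults
    spec: ModelSpec
    data: pd.DataFrame
    design_info: object
    shapiro_p: float
    singular: bool = False

    @property
    def fe_params(self) -> np.ndarray:
        return np.asarray(self.result.fe_params)

    @property
    def fe_cov(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]


def fit_mixed(table: pd.DataFrame, spec: ModelSpec = SPEED_MODEL,
              reml: bool = True) -> FittedModel:
    """Fit the mixed model described by ``spec`` to a measurement table.

    The response column is transformed per the spec before fitting.  A
    residual Shapiro–Wilk p-value is recorded (assumption check, not a
    gate).  Singular fits (a variance component collapsing to zero) are
    reported through ``singular`` and a warning, never hidden.
    """
    df = table.copy()
    if df["rat_id"].nunique() < 2:
        raise ValueError("random effect over rats needs at least 2 rats")
    df["y_t"] = apply_transform(df[spec.response].to_numpy(), spec.transform)

    y, x = patsy.dmatrices(spec.formula(), df, return_type="dataframe")
    design_info = x.design_info
    groups = df["rat_id"].to_numpy()
    if spec.random == "rat":
        model = MixedLM(np.asarray(y).ravel(), np.asarray(x), groups=groups)
    elif spec.random == "vessel_in_rat":
        vc = {"vessel_type": "0 + C(vessel_type)"}
        model = MixedLM.from_formula(
            spec.formula(), data=df, groups="rat_id", vc_formula=vc
        )
        design_info = model.data.design_info
    else:
        raise ValueError(f"unknown random-effects structure {spec.random!r}")

    result = None
    last_err: Exception | None = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            result = model.fit(reml=reml, method=method)
            if np.all(np.isfinite(np.asarray(result.fe_params))):
                break
        except (np.linalg.LinAlgError, ValueError) as exc:  # optimiser blew up
            last_err = exc
            result = None
    if result is None:
        raise RuntimeError(f"mixed-model fit failed: {last_err}")
    # marginal residuals y - X beta: robust even when a variance component
    # collapses to zero (conditional residuals are undefined there)
    resid = np.asarray(model.endog).ravel() - np.asarray(model.exog) @ np.asarray(
        result.fe_params
    )
    if len(resid) > 5000:
        resid = np.random.default_rng(0).choice(resid, 5000, replace=False)
    shapiro_p = float(sps.shapiro(resid).pvalue)
    re_var = float(np.asarray(result.cov_re).ravel().max()) if result.cov_re.size else 0.0
    singular = re_var < 1e-8 * float(result.scale)
    if singular:
        logger.warning("mixed-model fit is singular: random-effect variance ~ 0")
    return FittedModel(
        result=result,
        spec=spec,
        data=df,
        design_info=design_info,
        shapiro_p=shapiro_p,
        singular=singular,
    )


def compare_fixed_effects(table: pd.DataFrame, candidates: list[ModelSpec]) -> ModelSpec:
    """Pick the most parsimonious fixed-effect set by ML-based AIC.

    Candidates are refitted under ML for comparability; the winner is
    meant to be refitted by REML (via :func:`fit_mixed`) for reporting.
    """
    best, best_aic = None, math.inf
    for spec in candidates:
        fit = fit_mixed(table, spec, reml=False)
        aic = float(fit.result.aic)
        if not math.isfinite(aic):
            logger.warning("candidate %s: degenerate ML fit (AIC %s); skipped",
                           spec.fixed, aic)
            continue
        if aic < best_aic:
            best, best_aic = spec, aic
    if best is None:
        raise RuntimeError("no candidate model produced a finite AIC")
    return best


# ---------------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------------


@dataclass
class EmmResult:
    """Layer-level marginal means and their one-tailed comparison."""

    by_layer: pd.DataFrame  # layer, emm_t, se_t, emm (back-transformed)
    contrast: dict = field(default_factory=dict)


def emmeans_layer(model: FittedModel, alternative: str = "SL>DL") -> EmmResult:
    """Estimated marginal means per layer over the vessel-type grid.

    The EMM of a layer is the unweighted average of that layer's
    vessel-type cell predictions on the transformed scale (every cell
    counts equally regardless of how many vessels fell in it); the SE
    follows from the fixed-effect covariance by the delta method.  The
    back-transformed point estimate applies the exact inverse transform
    (no smearing correction).  The layer comparison is reported with
    one- and two-tailed p-values; ``alternative`` fixes the one-tailed
    direction.
    """
    df = model.data
    layers = sorted(df["layer"].unique())
    vtypes = sorted(df["vessel_type"].unique())
    observed = {(l, v) for l, v in zip(df["layer"], df["vessel_type"])}

    cvecs: dict[str, np.ndarray] = {}
    for layer in layers:
        rows = []
        for vt in vtypes:
            if (layer, vt) not in observed:
                logger.warning("empty cell (%s, %s) excluded from the EMM grid",
                               layer, vt)
                continue
            cell = {"layer": layer, "vessel_type": vt}
            for col in df.columns:
                if col not in cell and df[col].dtype == object:
                    cell[col] = df[col].iloc[0]
            rows.append(cell)
        grid = pd.DataFrame(rows)
        x = np.asarray(patsy.dmatrix(model.design_info, grid))
        cvecs[layer] = x.mean(axis=0)

    beta = model.fe_params
    cov = model.fe_cov
    recs = []
    for layer in layers:
        c = cvecs[layer]
        emm_t = float(c @ beta)
        se_t = float(np.sqrt(c @ cov @ c))
        recs.append(
            {
                "layer": layer,
                "emm_transformed": emm_t,
                "se_transformed": se_t,
                "emm": invert_transform(emm_t, model.spec.transform),
            }
        )
    by_layer = pd.DataFrame(recs)

    contrast: dict = {}
    if "SL" in cvecs and "DL" in cvecs:
        d = cvecs["SL"] - cvecs["DL"]
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        z = est / se
        p_two = float(2.0 * sps.norm.sf(abs(z)))
        z_dir = z if alternative == "SL>DL" else -z
        contrast = {
            "estimate_transformed": est,
            "se": se,
            "z": z,
            "p_one_tailed": float(sps.norm.sf(z_dir)),
            "p_two_tailed": p_two,
            "alternative": alternative,
            "ratio": float(
                invert_transform(cvecs["SL"] @ beta, model.spec.transform)
                / invert_transform(cvecs["DL"] @ beta, model.spec.transform)
            ),
        }
    return EmmResult(by_layer=by_layer, contrast=contrast)


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    slope: float


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures correlation: common within-subject association.

    Equivalent to an ANCOVA of y on x with a separate intercept per
    subject and a shared slope: r_rm carries the slope's sign and the
    magnitude sqrt(SS_x / (SS_x + SS_err)) — identical to the Pearson
    correlation of x and y after subtracting subject means.  Degrees of
    freedom are N_obs − N_subjects − 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if len(x) != len(y) or len(x) != len(subject):
        raise ValueError("x, y and subject must have equal length")
    subjects, inverse = np.unique(subject, return_inverse=True)
    if len(subjects) < 2:
        raise ValueError("rmcorr needs at least 2 subjects")
    counts = np.bincount(inverse)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 paired observations in >= 2 subjects")

    def centre(v: np.ndarray) -> np.ndarray:
        sums = np.bincount(inverse, weights=v)
        return v - (sums / counts)[inverse]

    xc, yc = centre(x), centre(y)
    ss_x = float(xc @ xc)
    if ss_x == 0 or float(yc @ yc) == 0:
        raise ValueError("x or y constant within every subject")
    slope = float(xc @ yc) / ss_x
    resid = yc - slope * xc
    ss_eff = slope * slope * ss_x
    ss_err = float(resid @ resid)
    r = math.copysign(math.sqrt(ss_eff / (ss_eff + ss_err)), slope)
    df = len(x) - len(subjects) - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrResult(r=r, df=df, p=p, slope=slope)


# ---------------------------------------------------------------------------
# Simulation utilities (model-layer validation)
# ---------------------------------------------------------------------------


def simulate_speed_table(
    seed: int,
    n_rats: int = 8,
    vessels_per_cell: int = 3,
    layers: tuple[str, ...] = ("SL", "DL"),
    vessel_types: tuple[str, ...] = ("A3", "C", "Vc", "V3"),
    dl_mean_um_s: float = 1600.0,
    sl_dl_ratio: float = 1.5,
    rat_sd_log: float = 0.25,
    resid_sd_log: float = 0.45,
    type_effects_log: tuple[float, ...] = (0.5, -0.3, -0.15, 0.1),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a log-normal speed table at a realistic study design.

    Defaults mimic the targeted study's design: 8 rats, two retinal
    layers, four vessel-type categories with ~12 vessels per layer per
    rat, a deep-layer typical speed of ~1600 µm/s, and a superficial
    layer faster by the stated ratio on the log scale.  Returns the
    long-format table and the ground-truth parameters.
    """
    rng = np.random.default_rng(seed)
    rat_effects = rng.normal(0.0, rat_sd_log, size=n_rats)
    rows = []
    for ri in range(n_rats):
        for layer in layers:
            for vt, vt_eff in zip(vessel_types, type_effects_log):
                for j in range(vessels_per_cell):
                    mu = (
                        math.log(dl_mean_um_s)
                        + (math.log(sl_dl_ratio) if layer == "SL" else 0.0)
                        + vt_eff
                        + rat_effects[ri]
                    )
                    rows.append(
                        {
                            "rat_id": f"rat{ri + 1}",
                            "layer": layer,
                            "vessel_type": vt,
                            "vessel_id": f"r{ri + 1}_{layer}_{vt}_{j}",
                            "window_index": 0,
                            "value": float(
                                np.exp(mu + rng.normal(0.0, resid_sd_log))
                            ),
                            "value_kind": "speed_um_s",
                            "method": "invivo",
                        }
                    )
    truth = {
        "layer_effect_log": math.log(sl_dl_ratio),
        "dl_mean_um_s": dl_mean_um_s,
        "rat_sd_log": rat_sd_log,
        "resid_sd_log": resid_sd_log,
    }
    return pd.DataFrame(rows), truth
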