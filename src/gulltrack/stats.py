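"""Habitat effects on trip-level energetic costs: mixed-model inference.

Three trip-level responses proxy energetic cost — trip duration (h), time in
flapping flight (h), and hourly energy expenditure (kJ/h).  Each is
transformed for normality (log, square root, log respectively) and modelled
as

    transform(y_ij) = beta_{category(ij)} + a_i + e_ij,

a linear mixed model with habitat category (urban reference, 5 levels) as
fixed effect and a random intercept a_i per bird.  The fitted model is
compared against a random-intercept-only null by a likelihood-ratio test on
ML fits and by Delta-AICc; pairwise category contrasts get a Tukey
(studentized-range) adjustment and compact letter groupings; variance
explained is summarised with Nakagawa's marginal and conditional R-squared:

    R2m = s2_f / (s2_f + s2_a + s2_e),
    R2c = (s2_f + s2_a) / (s2_f + s2_a + s2_e),

where s2_f is the variance of the fixed-effect predictions, s2_a the
between-bird variance and s2_e the residual variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

CATEGORIES = ("urban", "marine", "intertidal", "terrestrial", "mixed")

TRANSFORMS = {
    "duration_h": ("log", np.log),
    "flapping_h": ("sqrt", np.sqrt),
    "rate_kJ_h": ("log", np.log),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model and how it is transformed."""

    response: str = "rate_kJ_h"
    reference: str = "urban"

    def __post_init__(self) -> None:
        if self.response not in TRANSFORMS:
            raise ValueError(f"response must be one of {tuple(TRANSFORMS)}")

    @property
    def transform_name(self) -> str:
        return TRANSFORMS[self.response][0]

    @property
    def transform(self):
        return TRANSFORMS[self.response][1]


def transform_response(trip_table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """One model row per kept trip: transformed response, category, bird id.

    log-transformed responses must be strictly positive; sqrt admits zero
    (a trip can contain no flapping at all).
    """
    required = {"bird_id", "category", spec.response}
    missing = required - set(trip_table.columns)
    if missing:
        raise ValueError(f"trip table lacks columns {missing}")
    y = trip_table[spec.response].to_numpy(float)
    if spec.transform_name == "log":
        bad = y <= 0
    else:
        bad = y < 0
    if bad.any():
        ids = trip_table.index[bad].tolist()
        raise ValueError(
            f"{spec.transform_name} transform undefined for trips {ids} "
            f"(non-positive {spec.response})")
    present = set(trip_table["category"].unique())
    ordered = [spec.reference] + [c for c in CATEGORIES if c != spec.reference]
    levels = [c for c in ordered if c in present]
    levels += sorted(present - set(levels))   # tolerate non-standard labels
    return pd.DataFrame({
        "y": spec.transform(y),
        "category": pd.Categorical(trip_table["category"], categories=levels),
        "bird_id": trip_table["bird_id"].to_numpy(),
    })


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2 * llf + 2 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class HabitatEffectsResults:
    """Estimates, tests and variance components of the fitted mixed model."""

    spec: ModelSpec
    fixed_effects: pd.DataFrame          # estimate, se per term
    sigma2_a: float                      # between-bird variance
    sigma2_e: float                      # residual variance
    sigma2_f: float                      # fixed-effects variance
    loglik: float                        # ML log-likelihood of the full model
    loglik_null: float
    chisq: float
    df: int
    p_value: float
    delta_aicc: float
    letters: dict[str, str]              # compact letter display per category
    pairwise: pd.DataFrame               # contrast, estimate, se, p_adj
    n_obs: int
    n_birds: int
    singular: bool = False
    warnings_: list[str] = field(default_factory=list)

    @property
    def r2_marginal(self) -> float:
        return r2_mixed(self.sigma2_f, self.sigma2_a, self.sigma2_e)[0]

    @property
    def r2_conditional(self) -> float:
        return r2_mixed(self.sigma2_f, self.sigma2_a, self.sigma2_e)[1]

    def category_means(self) -> pd.Series:
        """Model-implied mean of the transformed response per category."""
        inter = self.fixed_effects.loc["Intercept", "estimate"]
        out = {}
        for cat in CATEGORIES:
            term = f"category[T.{cat}]"
            out[cat] = inter + (self.fixed_effects.loc[term, "estimate"]
                                if term in self.fixed_effects.index else 0.0)
        return pd.Series(out)

    def summary(self) -> str:
        lines = [
            f"Mixed model: {self.spec.transform_name}({self.spec.response}) "
            f"~ category + (1 | bird_id)",
            f"n = {self.n_obs} trips, {self.n_birds} birds",
            "",
            f"{'term':<26}{'estimate':>10}{'SE':>8}  letters",
        ]
        for term, row in self.fixed_effects.iterrows():
            cat = term.replace("category[T.", "").rstrip("]")
            cat = self.spec.reference if term == "Intercept" else cat
            lines.append(f"{term:<26}{row['estimate']:>10.3f}{row['se']:>8.3f}"
                         f"  {self.letters.get(cat, '')}")
        lines += [
            "",
            f"LRT vs null: chi2({self.df}) = {self.chisq:.2f}, "
            f"p = {self.p_value:.3g}, dAICc = {self.delta_aicc:.2f}",
            f"variances: bird {self.sigma2_a:.4f}, residual {self.sigma2_e:.4f}, "
            f"fixed {self.sigma2_f:.4f}",
            f"R2 marginal = {self.r2_marginal:.3f}, "
            f"conditional = {self.r2_conditional:.3f}",
        ]
        if self.singular:
            lines.append("note: singular fit (between-bird variance ~ 0)")
        return "\n".join(lines)


class HabitatEffectsModel:
    """Random-intercept linear model of a transformed trip response.

    Parameters
    ----------
    trip_table : one row per kept trip with columns ``bird_id``,
        ``category`` and the response named by `spec`.
    spec : the response/transform recipe.

    Estimation delegates to statsmodels ``MixedLM``: REML for the reported
    estimates, ML refits for the likelihood-ratio test and AICc.
    """

    def __init__(self, trip_table: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        self.spec = spec
        self.data = transform_response(trip_table, spec)
        if self.data["bird_id"].nunique() < 2:
            raise ValueError("random intercept needs at least two birds")
        if self.data["category"].nunique() < 2:
            raise ValueError("need at least two habitat categories")

    @classmethod
    def from_trip_table(cls, trip_table: pd.DataFrame, response: str = "rate_kJ_h"):
        return cls(trip_table, ModelSpec(response=response))

    def fit(self, alpha: float = 0.05) -> HabitatEffectsResults:
        data = self.data
        warns: list[str] = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            full_reml = sm.MixedLM.from_formula(
                "y ~ category", groups="bird_id", data=data).fit(reml=True)
            full_ml = sm.MixedLM.from_formula(
                "y ~ category", groups="bird_id", data=data).fit(reml=False)
            null_ml = sm.MixedLM.from_formula(
                "y ~ 1", groups="bird_id", data=data).fit(reml=False)
        warns.extend(str(w.message) for w in wlist
                     if "converge" in str(w.message).lower())

        fe = pd.DataFrame({
            "estimate": full_reml.fe_params,
            "se": full_reml.bse_fe,
        })
        sigma2_a = float(full_reml.cov_re.iloc[0, 0])
        sigma2_e = float(full_reml.scale)
        singular = sigma2_a < 1e-8
        fitted_fixed = np.asarray(
            full_reml.model.exog @ full_reml.fe_params.to_numpy())
        sigma2_f = float(np.var(fitted_fixed))

        n = len(data)
        chisq = max(0.0, 2 * (full_ml.llf - null_ml.llf))
        df = int(full_ml.k_fe - null_ml.k_fe)
        p = float(sps.chi2.sf(chisq, df))
        aicc_full = _aicc(full_ml.llf, full_ml.k_fe + 2, n)
        aicc_null = _aicc(null_ml.llf, null_ml.k_fe + 2, n)
        delta_aicc = aicc_null - aicc_full

        pairwise, letters = self._tukey_letters(full_reml, alpha=alpha)
        return HabitatEffectsResults(
            spec=self.spec,
            fixed_effects=fe,
            sigma2_a=sigma2_a, sigma2_e=sigma2_e, sigma2_f=sigma2_f,
            loglik=float(full_ml.llf), loglik_null=float(null_ml.llf),
            chisq=chisq, df=df, p_value=p, delta_aicc=delta_aicc,
            letters=letters, pairwise=pairwise,
            n_obs=n, n_birds=int(data["bird_id"].nunique()),
            singular=singular, warnings_=warns,
        )

    def _tukey_letters(self, fitted, alpha: float):
        """All pairwise category contrasts with a studentized-range
        adjustment, and the derived compact letter display."""
        cats = [c for c in self.data["category"].cat.categories
                if (self.data["category"] == c).any()]
        params = fitted.fe_params
        cov = fitted.cov_params().iloc[:len(params), :len(params)]
        names = list(params.index)

        def cvec(cat):
            v = np.zeros(len(names))
            term = f"category[T.{cat}]"
            if term in names:
                v[names.index(term)] = 1.0
            return v

        k = len(cats)
        rows = []
        sig = {}
        for a, b in itertools.combinations(cats, 2):
            c = cvec(a) - cvec(b)
            est = float(c @ params.to_numpy())
            se = float(np.sqrt(c @ cov.to_numpy() @ c))
            if se == 0:
                p_adj = 1.0
            else:
                # studentized-range adjustment with large-sample df
                q = abs(est) / se * np.sqrt(2)
                dfres = max(len(self.data) - len(names), 1)
                p_adj = float(sps.studentized_range.sf(q, k, dfres))
            rows.append({"contrast": f"{a} - {b}", "estimate": est,
                         "se": se, "p_adj": p_adj})
            sig[(a, b)] = sig[(b, a)] = p_adj < alpha
        letters = _compact_letters(cats, sig)
        return pd.DataFrame(rows), letters


def _compact_letters(groups: list, sig: dict) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ."""
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(not sig.get((g, other), False) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant sets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in s:
                out[g] += ch
    return out


def r2_mixed(sigma2_f: float, sigma2_a: float, sigma2_e: float) -> tuple[float, float]:
    """Marginal and conditional R-squared from variance components."""
    tot = sigma2_f + sigma2_a + sigma2_e
    if tot <= 0:
        raise ValueError("all variance components are zero")
    return sigma2_f / tot, (sigma2_f + sigma2_a) / tot


def lrt_p_value(trip_table: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> float:
    """Likelihood-ratio p-value of the habitat effect (ML fits only).

    Lighter than :meth:`HabitatEffectsModel.fit` when only the null
    comparison is needed, e.g. in repeated-simulation calibration studies.
    """
    data = transform_response(trip_table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM.from_formula(
            "y ~ category", groups="bird_id", data=data).fit(reml=False)
        null = sm.MixedLM.from_formula(
            "y ~ 1", groups="bird_id", data=data).fit(reml=False)
    chisq = max(0.0, 2 * (full.llf - null.llf))
    return float(sps.chi2.sf(chisq, int(full.k_fe - null.k_fe)))


def simulate_trip_responses(
    effects: dict[str, float],
    n_trips: int = 605,
    n_birds: int = 17,
    sigma_bird: float = 0.3,
    sigma_resid: float = 0.5,
    category_probs: dict[str, float] | None = None,
    seed: int = 0,
    response: str = "duration_h",
) -> pd.DataFrame:
    """Trip table with planted category effects on the transformed scale.

    Used for parameter-recovery and type-I-error studies of the inferential
    stage without running the full GPS pipeline.  `effects` maps category ->
    true effect relative to the urban intercept on the transformed scale.
    """
    rng = np.random.default_rng(seed)
    cats = list(effects)
    probs = np.array([
        (category_probs or {}).get(c, 1.0) for c in cats], float)
    probs /= probs.sum()
    bird = rng.integers(0, n_birds, n_trips)
    bird_re = rng.normal(0, sigma_bird, n_birds)
    cat = rng.choice(cats, size=n_trips, p=probs)
    intercept = 1.0
    y_t = (intercept
           + np.array([effects[c] for c in cat])
           + bird_re[bird]
           + rng.normal(0, sigma_resid, n_trips))
    name, fwd = TRANSFORMS[response]
    y = np.exp(y_t) if name == "log" else y_t**2
    return pd.DataFrame({
        "bird_id": [f"gull{i:02d}" for i in bird],
        "category": cat,
        response: y,
    })
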