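"""Polynomial risk scores and the GIM search.

GIM (generalized iterative modelling) searches over polynomial combinations
of covariates for the combination that maximizes a fitness function — here
the Cox partial likelihood of a right-censored time-to-event outcome.  The
result is a :class:`PolynomialScore`: a sum of monomial terms
``coefficient * variable**power`` whose value is the log relative hazard of
a patient.  The published HCC risk score (age + quadratics in plasma
phenylalanine and glutamine, both in μM) ships as a packaged fixture.

The search itself is a penalized greedy forward(-backward) selection over
candidate monomials: at every step each unused monomial is tried by jointly
refitting all coefficients with a Cox model, the model is scored by an
information criterion (BIC by default, with the number of events as the
effective sample size), and the best improving monomial is added.

Candidate monomials are powers of the *centered* variable, standardized to
unit variance.  Raw powers of a positive-valued covariate are nearly
collinear over a physiological range (corr(x, x^2) is typically > 0.99 for
plasma concentrations), which makes raw-basis selection a coin flip between
algebraically equivalent representations; centered powers are close to
orthogonal, so the search sees each degree's independent signal.  The
selected centered polynomial is expanded exactly (binomial theorem) back to
raw-scale ``coefficient * variable**power`` terms on output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .io import float_repr
from .survival import CoxPH, CoxPHResults, SurvivalData, cox_partial_loglik

__all__ = [
    "PolynomialScore",
    "GimConfig",
    "GIMSearch",
    "GIMResults",
    "published_risk_score",
    "evaluate_score",
    "gim_search",
    "score_hazard_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolynomialScore:
    """A polynomial risk score: sum of ``coefficient * variable**power`` terms.

    Parameters
    ----------
    terms
        Sequence of ``(variable_name, power, coefficient)`` with integer
        ``power >= 1`` and no duplicate ``(variable, power)`` pair.
    intercept
        Additive constant, default 0.  Location shifts do not change Cox
        hazard ratios but keep standardized and raw-scale evaluations equal.
    """

    terms: tuple[tuple[str, int, float], ...]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        norm = []
        seen = set()
        for var, power, coef in self.terms:
            power = int(power)
            if power < 1:
                raise ValueError(f"term {var!r} has power {power}; powers must be >= 1")
            key = (str(var), power)
            if key in seen:
                raise ValueError(f"duplicate term {var}^{power}")
            seen.add(key)
            norm.append((str(var), power, float(coef)))
        object.__setattr__(self, "terms", tuple(norm))
        object.__setattr__(self, "intercept", float(self.intercept))

    @property
    def variables(self) -> tuple[str, ...]:
        """Distinct variable names used by the score, in first-use order."""
        out: list[str] = []
        for var, _, _ in self.terms:
            if var not in out:
                out.append(var)
        return tuple(out)

    def __call__(self, row: Mapping[str, float] | pd.DataFrame | pd.Series):
        return evaluate_score(self, row)

    def to_frame(self) -> pd.DataFrame:
        """Terms as a (variable, power, coefficient) DataFrame."""
        return pd.DataFrame(self.terms, columns=["variable", "power", "coefficient"])

    def to_csv(self, path) -> None:
        """Serialize as CSV; the intercept, if nonzero, is an extra row with
        variable ``"(intercept)"`` and power 0."""
        frame = self.to_frame()
        if self.intercept != 0.0:
            extra = pd.DataFrame(
                [("(intercept)", 0, self.intercept)],
                columns=["variable", "power", "coefficient"],
            )
            frame = pd.concat([frame, extra], ignore_index=True)
        frame.to_csv(path, index=False, float_format=float_repr)

    @classmethod
    def from_csv(cls, path) -> "PolynomialScore":
        frame = pd.read_csv(path)
        missing = {"variable", "power", "coefficient"} - set(frame.columns)
        if missing:
            raise ValueError(f"score CSV missing columns: {sorted(missing)}")
        intercept = 0.0
        terms = []
        for _, row in frame.iterrows():
            if row["variable"] == "(intercept)":
                intercept = float(row["coefficient"])
            else:
                terms.append((row["variable"], int(row["power"]), float(row["coefficient"])))
        return cls(tuple(terms), intercept=intercept)


def published_risk_score() -> PolynomialScore:
    """The published HCC risk score.

    ``R = 0.0694*age + 0.3399*Phe − 0.00188154*Phe² − 0.0133*Gln
    + 0.00002244*Gln²`` with age in years and phenylalanine/glutamine plasma
    concentrations in μM.  Loaded from the packaged CSV so that the shipped
    artifact and the in-memory fixture cannot drift apart.
    """
    ref = resources.files("metabosurv").joinpath("data/hcc_risk_score.csv")
    with resources.as_file(ref) as path:
        return PolynomialScore.from_csv(path)


def evaluate_score(score: PolynomialScore, row) -> float | np.ndarray:
    """Evaluate a polynomial score on a mapping, Series, or DataFrame of
    covariate values.

    Returns a scalar for a single row, an ndarray for a DataFrame.  Raises
    ``KeyError`` naming the first missing variable.
    """
    if isinstance(row, pd.DataFrame):
        getter = lambda v: row[v].to_numpy(dtype=float)  # noqa: E731
        present = row.columns
        total = np.full(len(row), float(score.intercept))
    else:
        getter = lambda v: float(row[v])  # noqa: E731
        present = row.keys() if isinstance(row, Mapping) else row.index
        total = float(score.intercept)
    for var, _, _ in score.terms:
        if var not in present:
            raise KeyError(f"score variable {var!r} missing from input row")
    for var, power, coef in score.terms:
        total = total + coef * getter(var) ** power
    return total


@dataclass(frozen=True)
class GimConfig:
    """Configuration of the GIM monomial search.

    ``selection_penalty`` is "BIC" (penalty ``log(n_events)`` per term; the
    number of events is the effective sample size of a partial likelihood) or
    "AIC" (penalty 2).  ``tie_tolerance`` is the minimum criterion improvement
    counted as real, guarding floating-point non-determinism.
    """

    candidate_variables: tuple[str, ...]
    max_degree: int = 2
    max_terms: int = 8
    selection_penalty: str = "BIC"
    forward_backward: bool = True
    tie_tolerance: float = 1e-10
    forced_terms: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidate_variables", tuple(self.candidate_variables))
        object.__setattr__(
            self, "forced_terms", tuple((str(v), int(p)) for v, p in self.forced_terms)
        )
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.selection_penalty not in ("AIC", "BIC"):
            raise ValueError("selection_penalty must be 'AIC' or 'BIC'")
        if not self.candidate_variables:
            raise ValueError("candidate_variables must be non-empty")


def _monomial_name(var: str, power: int) -> str:
    return var if power == 1 else f"{var}^{power}"


class GIMSearch:
    """Model object for the GIM polynomial search on right-censored data.

    Parameters
    ----------
    data
        :class:`~metabosurv.survival.SurvivalData` whose covariate frame
        contains every candidate variable.
    config
        :class:`GimConfig`.

    ``fit()`` returns :class:`GIMResults` holding the selected
    :class:`PolynomialScore`, the audit trace, and the final Cox fit on the
    selected (standardized) monomial design.
    """

    def __init__(self, data: SurvivalData, config: GimConfig):
        self.data = data
        self.config = config
        missing = [v for v in config.candidate_variables if v not in data.covariates.columns]
        if missing:
            raise ValueError(f"candidate variables not in data: {missing}")
        for v in config.candidate_variables:
            col = data.covariates[v].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                raise ValueError(f"candidate variable {v!r} is constant")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        duration_col: str,
        event_col: str,
        config: GimConfig,
    ) -> "GIMSearch":
        data = SurvivalData.from_dataframe(
            frame, duration_col, event_col, list(config.candidate_variables)
        )
        return cls(data, config)

    # -- internals ---------------------------------------------------------

    def _monomial_columns(self):
        """Standardized centered-basis monomial columns keyed by
        (variable, power), in lexicographic order (the deterministic
        tie-break order).  ``stats[key] = (center, mono_mean, mono_sd)``."""
        cfg = self.config
        cols: dict[tuple[str, int], np.ndarray] = {}
        stats: dict[tuple[str, int], tuple[float, float, float]] = {}
        for var in sorted(cfg.candidate_variables):
            raw = self.data.covariates[var].to_numpy(dtype=float)
            center = float(raw.mean())
            for power in range(1, cfg.max_degree + 1):
                mono = (raw - center) ** power
                mu = float(mono.mean())
                sd = float(mono.std(ddof=1))
                if sd == 0.0 or not math.isfinite(sd):
                    logger.warning("monomial %s is degenerate; skipped", _monomial_name(var, power))
                    continue
                cols[(var, power)] = (mono - mu) / sd
                stats[(var, power)] = (center, mu, sd)
        return cols, stats

    def _fit_subset(self, keys, cols):
        names = [_monomial_name(v, p) for v, p in keys]
        design = pd.DataFrame({n: cols[k] for n, k in zip(names, keys)})
        data = SurvivalData(self.data.time, self.data.event, design)
        return CoxPH(data).fit()

    def _criterion(self, llf: float, n_terms: int) -> float:
        if self.config.selection_penalty == "BIC":
            penalty = math.log(self.data.n_events)
        else:
            penalty = 2.0
        return -2.0 * llf + penalty * n_terms

    def fit(self) -> "GIMResults":
        cfg = self.config
        cols, stats = self._monomial_columns()
        if not cols:
            raise ValueError("no usable candidate monomials")

        current: list[tuple[str, int]] = []
        for key in cfg.forced_terms:
            if key not in cols:
                raise ValueError(f"forced term {key} is not a usable monomial")
            current.append(key)

        null_llf = cox_partial_loglik(
            SurvivalData(self.data.time, self.data.event, pd.DataFrame(index=range(len(self.data.time)))),
            np.zeros(0),
        )
        if current:
            res = self._fit_subset(current, cols)
            best_llf, criterion = res.llf, self._criterion(res.llf, len(current))
        else:
            best_llf, criterion = null_llf, self._criterion(null_llf, 0)

        trace: list[dict] = []
        step = 0

        def log_step(action: str, key, llf: float, crit: float) -> None:
            nonlocal step
            step += 1
            trace.append(
                {
                    "step": step,
                    "action": action,
                    "term": _monomial_name(*key),
                    "log_partial_likelihood": llf,
                    "penalized_criterion": crit,
                }
            )

        while len(current) < cfg.max_terms:
            fits = {}
            for key in cols:  # lexicographic order by construction
                if key in current:
                    continue
                try:
                    res = self._fit_subset(current + [key], cols)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning("candidate %s skipped: %s", _monomial_name(*key), exc)
                    continue
                if not res.converged:
                    logger.warning(
                        "candidate %s skipped: %s", _monomial_name(*key), res.message
                    )
                    continue
                fits[key] = res
            if not fits:
                break
            crits = {k: self._criterion(r.llf, len(current) + 1) for k, r in fits.items()}
            best_crit = min(crits.values())
            if criterion - best_crit <= cfg.tie_tolerance:
                break
            # deterministic tie-break: lexicographically first within tolerance
            chosen = next(k for k in crits if crits[k] <= best_crit + cfg.tie_tolerance)
            res = fits[chosen]
            if res.llf < best_llf - 1e-8:
                raise AssertionError("partial log-likelihood decreased on an add step")
            current.append(chosen)
            best_llf, criterion = res.llf, crits[chosen]
            log_step("add", chosen, best_llf, criterion)

            if cfg.forward_backward:
                improved = True
                while improved and len(current) > 1:
                    improved = False
                    droppable = [k for k in current if k not in cfg.forced_terms]
                    drop_fits = {}
                    for key in sorted(droppable):
                        subset = [k for k in current if k != key]
                        try:
                            drop_fits[key] = self._fit_subset(subset, cols)
                        except (ValueError, np.linalg.LinAlgError):
                            continue
                    drop_crits = {
                        k: self._criterion(r.llf, len(current) - 1)
                        for k, r in drop_fits.items()
                        if r.converged
                    }
                    if not drop_crits:
                        break
                    best_drop = min(drop_crits.values())
                    if criterion - best_drop > cfg.tie_tolerance:
                        key = next(
                            k for k in drop_crits if drop_crits[k] <= best_drop + cfg.tie_tolerance
                        )
                        current.remove(key)
                        res = drop_fits[key]
                        best_llf, criterion = res.llf, drop_crits[key]
                        log_step("drop", key, best_llf, criterion)
                        improved = True

        if not current:
            raise ValueError("no candidate monomial improved the selection criterion")

        final = self._fit_subset(current, cols)
        # expand the selected centered polynomial exactly to the raw scale:
        # beta * ((x - c)^p - mu)/sd  =  (beta/sd) * sum_k C(p,k) x^k (-c)^(p-k)
        #                                - beta*mu/sd
        intercept = 0.0
        raw_coefs: dict[tuple[str, int], float] = {}
        for key in current:
            var, power = key
            c, mu, sd = stats[key]
            beta = float(final.params[_monomial_name(*key)])
            scale = beta / sd
            intercept -= beta * mu / sd
            for k in range(0, power + 1):
                contrib = scale * math.comb(power, k) * (-c) ** (power - k)
                if k == 0:
                    intercept += contrib
                else:
                    raw_coefs[(var, k)] = raw_coefs.get((var, k), 0.0) + contrib
        terms = tuple(
            (var, k, coef) for (var, k), coef in sorted(raw_coefs.items()) if coef != 0.0
        )
        score = PolynomialScore(terms, intercept=intercept)
        trace_frame = pd.DataFrame(
            trace,
            columns=["step", "action", "term", "log_partial_likelihood", "penalized_criterion"],
        )
        return GIMResults(score=score, trace=trace_frame, final_fit=final, config=cfg)


@dataclass
class GIMResults:
    """Result of :meth:`GIMSearch.fit`.

    Attributes
    ----------
    score
        The selected :class:`PolynomialScore` on the raw covariate scale.
    trace
        Audit trail of add/drop steps with the partial log-likelihood and the
        penalized criterion after each step.
    final_fit
        :class:`~metabosurv.survival.CoxPHResults` of the final standardized
        monomial design.
    """

    score: PolynomialScore
    trace: pd.DataFrame
    final_fit: CoxPHResults
    config: GimConfig

    def summary(self) -> str:
        lines = ["GIM polynomial search", "=" * 21]
        lines.append(f"penalty: {self.config.selection_penalty}   terms: {len(self.score.terms)}")
        lines.append(f"final log partial likelihood: {self.final_fit.llf:.6f}")
        lines.append("")
        lines.append(f"{'term':<20}{'coefficient':>16}")
        for var, power, coef in self.score.terms:
            lines.append(f"{_monomial_name(var, power):<20}{coef:>16.8g}")
        return "\n".join(lines)


def gim_search(data: SurvivalData, config: GimConfig):
    """Functional wrapper: returns ``(PolynomialScore, trace DataFrame)``."""
    res = GIMSearch(data, config).fit()
    return res.score, res.trace


def score_hazard_ratio(data: SurvivalData | pd.DataFrame, score: PolynomialScore,
                       duration_col: str = "time_years", event_col: str = "event") -> CoxPHResults:
    """Fit a single-covariate Cox model on the evaluated score.

    The returned fit's hazard ratio is the relative hazard per unit of the
    score.  Raises ``ValueError`` if the score is constant on the data.
    """
    if isinstance(data, SurvivalData):
        frame = data.covariates.copy()
        time, event = data.time, data.event
    else:
        frame = data
        time = data[duration_col].to_numpy(dtype=float)
        event = data[event_col].to_numpy()
    values = np.asarray(evaluate_score(score, frame), dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("risk score is constant on this data; cannot fit a hazard ratio")
    design = pd.DataFrame({"risk_score": values})
    sdata = SurvivalData(np.asarray(time, dtype=float), np.asarray(event), design)
    return CoxPH(sdata).fit()
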