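"""Experiment protocol: train/test split, ensemble, scenario comparison.

Orchestrates the study protocol around the network core: a chronological
train/test split of the monthly stream (training Jan 2015 - May 2019, test
Jun - Dec 2019 by default, everything before 2020 to exclude pandemic
excess), a 25-member ensemble of independently initialized networks whose
mean and spread quantify robustness, predictions for warmer-world scenario
inputs, and scenario-minus-observed rate differences with seasonal
aggregates and conversion to absolute monthly deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import esn
from .preprocess import (
    GridOrder,
    Month,
    MortalitySeries,
    NormalizationSpec,
    TemperatureFieldSeries,
    flatten_inputs,
    format_month,
    month_index,
    month_range,
    normalize_temperature,
)

SUMMER_MONTHS = (6, 7, 8)
WINTER_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class ExperimentPlan:
    """Spans, ensemble size and seed bookkeeping of one experiment.

    Spans are inclusive (start, end) pairs of (year, month).  Defaults:
    training Jan 2015 - May 2019 (53 months), test Jun - Dec 2019
    (7 months), scenario predictions Jan 2017 - Dec 2019, 25 ensemble
    members seeded ``base_seed + member_index``.
    """

    train_span: tuple[Month, Month] = ((2015, 1), (2019, 5))
    test_span: tuple[Month, Month] = ((2019, 6), (2019, 12))
    scenario_span: tuple[Month, Month] = ((2017, 1), (2019, 12))
    ensemble_size: int = 25
    base_seed: int = 0
    summer_months: tuple[int, ...] = SUMMER_MONTHS
    winter_months: tuple[int, ...] = WINTER_MONTHS

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        for name in ("train_span", "test_span", "scenario_span"):
            start, end = getattr(self, name)
            if month_index(end) < month_index(start):
                raise ValueError(f"{name} ends before it starts")
            if end[0] >= 2020:
                raise ValueError(
                    f"{name} must end before 2020, got {format_month(end)}")

    @property
    def train_months(self) -> list[Month]:
        return month_range(*self.train_span)

    @property
    def test_months(self) -> list[Month]:
        return month_range(*self.test_span)

    @property
    def scenario_months(self) -> list[Month]:
        return month_range(*self.scenario_span)

    def member_seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.ensemble_size)]

    def replace(self, **kwargs) -> "ExperimentPlan":
        from dataclasses import replace as _replace
        return _replace(self, **kwargs)


@dataclass
class EnsemblePrediction:
    """Per-member monthly predictions with ensemble mean and spread.

    ``member_outputs`` has shape (n_members, n_months); ``sd`` is the
    population standard deviation across members (zero for a single
    member).
    """

    months: list[Month]
    member_outputs: np.ndarray
    scenario: str = "reference"

    def __post_init__(self) -> None:
        self.member_outputs = np.atleast_2d(
            np.asarray(self.member_outputs, dtype=float))
        if self.member_outputs.shape[1] != len(self.months):
            raise ValueError(
                f"{self.member_outputs.shape[1]} prediction columns for "
                f"{len(self.months)} months")

    @property
    def n_members(self) -> int:
        return self.member_outputs.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.member_outputs.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.member_outputs.std(axis=0, ddof=0)


@dataclass
class ScenarioComparison:
    """Scenario-mean minus observed-rate differences and their aggregates.

    ``monthly_diff`` is the scenario ensemble mean minus the observed
    (reference-period) rate, per aligned month; ``absolute_deaths`` the
    conversion to additional deaths per month via the population.
    """

    months: list[Month]
    monthly_diff: np.ndarray
    population: np.ndarray
    scenario: str
    summer_months: tuple[int, ...] = SUMMER_MONTHS
    winter_months: tuple[int, ...] = WINTER_MONTHS

    @property
    def absolute_deaths(self) -> np.ndarray:
        return rate_to_absolute_deaths(self.monthly_diff, self.population)

    def _seasonal_mean(self, season: tuple[int, ...]) -> float:
        mask = np.array([m in season for _, m in self.months])
        if not mask.any():
            raise ValueError("no aligned months fall in the requested season")
        return float(self.monthly_diff[mask].mean())

    @property
    def summer_mean_diff(self) -> float:
        """Mean Jun-Aug rate difference (per 100,000 per month)."""
        return self._seasonal_mean(self.summer_months)

    @property
    def winter_mean_diff(self) -> float:
        """Mean Dec-Feb rate difference (per 100,000 per month)."""
        return self._seasonal_mean(self.winter_months)


def rate_to_absolute_deaths(rate_diff, population):
    """Additional deaths per month implied by a per-100,000 rate change."""
    return np.asarray(rate_diff, dtype=float) * \
        np.asarray(population, dtype=float) / 1e5


# ---------------------------------------------------------------------------
# Train/test protocol
# ---------------------------------------------------------------------------

def split_train_test(months: Sequence[Month], plan: ExperimentPlan,
                     ) -> tuple[list[int], list[int]]:
    """Chronological index split of a monthly stream into train and test.

    The two spans must be disjoint and contiguous (test starts the month
    after training ends) so the reservoir state can continue from the end
    of the training run into the test period.
    """
    train, test = plan.train_months, plan.test_months
    if month_index(test[0]) <= month_index(train[-1]):
        raise ValueError("test span overlaps or precedes the training span")
    if month_index(test[0]) != month_index(train[-1]) + 1:
        raise ValueError("gap between training and test spans")
    pos = {m: i for i, m in enumerate(months)}
    missing = [m for m in train + test if m not in pos]
    if missing:
        raise ValueError(
            f"series does not cover {[format_month(m) for m in missing]}")
    return [pos[m] for m in train], [pos[m] for m in test]


def train_test_member(config: esn.ESNConfig, inputs: np.ndarray,
                      targets: np.ndarray, plan: ExperimentPlan,
                      months: Sequence[Month],
                      ) -> tuple[esn.ESNWeights, np.ndarray]:
    """Train one member and predict the test span.

    The reservoir is driven once over the contiguous train+test stream;
    the readout is fitted on the training months (beyond the washout) and
    the test predictions use the states from the same run, so the state at
    test time continues from the end of training.
    """
    train_idx, test_idx = split_train_test(months, plan)
    stream = train_idx + test_idx
    weights = esn.init_esn(config, n_inputs=inputs.shape[1])
    activations = esn.run_reservoir(weights, inputs[stream])
    n_train = len(train_idx)
    trained = esn.train_readout(
        weights, inputs[train_idx], activations[:, :n_train],
        targets[train_idx])
    preds = esn.predict(trained, inputs[test_idx],
                        activations=activations[:, n_train:])
    return trained, preds


def run_ensemble(plan: ExperimentPlan, inputs: np.ndarray,
                 targets: np.ndarray, months: Sequence[Month],
                 config: esn.ESNConfig,
                 ) -> tuple[EnsemblePrediction, list[esn.ESNWeights]]:
    """Train the ensemble and collect test-span predictions.

    Members differ only in their initialization seed (``base_seed + i``);
    training data are never resampled, so results are identical whatever
    order the members are trained in.
    """
    members, outputs = [], []
    for seed in plan.member_seeds():
        cfg = config.replace(seed=seed)
        trained, preds = train_test_member(cfg, inputs, targets, plan, months)
        members.append(trained)
        outputs.append(preds)
    ens = EnsemblePrediction(months=plan.test_months,
                             member_outputs=np.vstack(outputs))
    return ens, members


def predict_scenario(members: Sequence[esn.ESNWeights], inputs: np.ndarray,
                     months: Sequence[Month], scenario: str,
                     washout: int | None = None) -> EnsemblePrediction:
    """Ensemble predictions for a scenario input stream.

    Scenario series are not temporally contiguous with the training
    stream, so each member's reservoir is run from a zero state through
    its own washout; the first ``washout`` months (default: the members'
    configured washout) are dropped from the returned predictions.
    """
    if len(members) == 0:
        raise ValueError("empty ensemble")
    cut = members[0].config.washout if washout is None else washout
    if cut >= len(months):
        raise ValueError(
            f"washout {cut} leaves no scenario months out of {len(months)}")
    outputs = [esn.predict(m, inputs)[cut:] for m in members]
    return EnsemblePrediction(months=list(months)[cut:],
                              member_outputs=np.vstack(outputs),
                              scenario=scenario)


def compare_scenarios(ens: EnsemblePrediction, reference: MortalitySeries,
                      population: float | np.ndarray | None = None,
                      summer_months: tuple[int, ...] = SUMMER_MONTHS,
                      winter_months: tuple[int, ...] = WINTER_MONTHS,
                      ) -> ScenarioComparison:
    """Scenario ensemble mean minus observed rates, aligned by month.

    The reference is the observed/target series of the current climate,
    not a reference-scenario prediction.  ``population`` defaults to the
    reference series' monthly population.
    """
    ref_pos = {m: i for i, m in enumerate(reference.months)}
    missing = [m for m in ens.months if m not in ref_pos]
    if missing:
        raise ValueError(
            "scenario months missing from the reference series: "
            f"{[format_month(m) for m in missing]}")
    idx = [ref_pos[m] for m in ens.months]
    diff = ens.mean - reference.rate[idx]
    if population is None:
        pop = reference.population[idx]
    else:
        pop = np.broadcast_to(np.asarray(population, dtype=float),
                              diff.shape).copy()
    return ScenarioComparison(months=list(ens.months), monthly_diff=diff,
                              population=pop, scenario=ens.scenario,
                              summer_months=summer_months,
                              winter_months=winter_months)


# ---------------------------------------------------------------------------
# Synthetic end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Bundle of one full synthetic train/evaluate/project run."""

    test_prediction: EnsemblePrediction
    test_error: esn.ErrorMetric
    comparisons: dict[str, ScenarioComparison]
    mortality: MortalitySeries
    members: list[esn.ESNWeights] = field(default_factory=list)


def run_synthetic_experiment(climate_spec, response_spec,
                             config: esn.ESNConfig,
                             plan: ExperimentPlan,
                             norm: NormalizationSpec = NormalizationSpec(),
                             scenario_offsets: Sequence[float] = (2.0, 4.0),
                             keep_members: bool = False) -> ExperimentResult:
    """Generate synthetic storylines, train the ensemble, evaluate the
    test span, and compare warmer-scenario predictions with the synthetic
    observations.

    ``climate_spec`` / ``response_spec`` are
    :class:`~esnmort.synthetic.SyntheticClimateSpec` /
    :class:`~esnmort.synthetic.SyntheticResponseSpec`; the reference
    stack must cover train+test, and each scenario stack the plan's
    scenario span.
    """
    from . import synthetic  # local import: generator is optional upstream

    ref_spec = climate_spec.replace(warming_offset=0.0)
    ref_temps = synthetic.generate_temperature_series(ref_spec)
    mortality = synthetic.generate_mortality_series(ref_temps, response_spec)

    inputs, order = flatten_inputs(normalize_temperature(ref_temps, norm))
    months = ref_temps.months
    targets = mortality.rate

    ens, members = run_ensemble(plan, inputs, targets, months, config)
    test_idx = [months.index(m) for m in plan.test_months]
    err = esn.rms_error(ens.mean, targets[test_idx])

    # scenario reservoirs are driven through the full synthetic input
    # stream and evaluated on the scenario span only, so their states are
    # as converged as the training states the readout was fitted on
    spin_up = months.index(plan.scenario_months[0])
    comparisons: dict[str, ScenarioComparison] = {}
    for w in scenario_offsets:
        spec_w = climate_spec.replace(warming_offset=float(w))
        temps_w = synthetic.generate_temperature_series(spec_w)
        in_w, _ = flatten_inputs(normalize_temperature(temps_w, norm), order)
        pred_w = predict_scenario(members, in_w, months,
                                  scenario=temps_w.scenario,
                                  washout=spin_up)
        pred_w = EnsemblePrediction(
            months=plan.scenario_months,
            member_outputs=pred_w.member_outputs[
                :, :len(plan.scenario_months)],
            scenario=pred_w.scenario)
        comparisons[temps_w.scenario] = compare_scenarios(
            pred_w, mortality,
            summer_months=plan.summer_months,
            winter_months=plan.winter_months)

    return ExperimentResult(
        test_prediction=ens, test_error=err, comparisons=comparisons,
        mortality=mortality, members=members if keep_members else [])
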