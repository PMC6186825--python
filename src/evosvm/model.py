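"""Model / results interface to the evolutionary weighted SVM ensemble.

:class:`EvolvingSVMEnsemble` is constructed from a labeled FC dataset (or
straight from per-subject time series); :meth:`~EvolvingSVMEnsemble.fit`
runs the full evolutionary loop and returns an :class:`EvolutionResults`
carrying the evolution history, the optimal generation's ensemble, the
held-out metric report and a ``summary()`` table.  Prediction, region
ranking, persistence and plotting hang off the results object.

Example
-------
>>> from evosvm import SyntheticSpec, generate_study, EvolvingSVMEnsemble
>>> study = generate_study(SyntheticSpec(seed=7))
>>> model = EvolvingSVMEnsemble.from_study(study, n_members=100, m=14,
...                                        q=1.5, n_evolutions=15)
>>> res = model.fit()
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .config import RunConfig, substream
from .connectivity import (
    LabeledFCDataset,
    ROITimeSeries,
    build_dataset,
    compute_fc_vector,
)
from .ensemble import SplitSpec, predict_batch, split_outer, vote_totals
from .evolution import EvolutionHistory, run_evolution
from .exceptions import InvalidStateError
from .metrics import MetricReport
from .persist import save_ensemble
from .regions import RegionFrequencyTable, RegionTable, region_frequencies

__all__ = ["EvolvingSVMEnsemble", "EvolutionResults"]


class EvolvingSVMEnsemble:
    """Evolutionary weighted random SVM ensemble classifier.

    Parameters
    ----------
    dataset
        Labeled FC features, one row per subject.
    config
        Full run configuration; keyword overrides are applied on top
        (``EvolvingSVMEnsemble(ds, n_members=100, q=1.5)``).
    """

    def __init__(self, dataset: LabeledFCDataset, config: RunConfig | None = None, **overrides):
        self.dataset = dataset
        cfg = config or RunConfig()
        if overrides:
            cfg = cfg.replace(**overrides)
        self.config = cfg

    @classmethod
    def from_time_series(
        cls,
        series: Sequence[ROITimeSeries],
        labels: Mapping[str, int],
        config: RunConfig | None = None,
        *,
        on_constant: str = "raise",
        **overrides,
    ) -> "EvolvingSVMEnsemble":
        """Build the FC dataset from raw region time series, then the model."""
        dataset = build_dataset(series, labels, on_constant=on_constant)
        return cls(dataset, config, **overrides)

    @classmethod
    def from_study(cls, study, config: RunConfig | None = None, **overrides):
        """Convenience constructor from a synthetic :class:`GeneratedStudy`."""
        return cls.from_time_series(study.series, study.labels, config, **overrides)

    def fit(self, seed: int | None = None) -> "EvolutionResults":
        """Run the evolutionary loop and return the fitted results.

        ``seed`` overrides ``config.seed`` for this fit only.
        """
        cfg = self.config if seed is None else self.config.replace(seed=int(seed))
        dataset = self.dataset
        scaler = None
        if cfg.standardize:
            # scaler is fit on the train+validation subjects only; the outer
            # split below is replayed identically inside run_evolution
            spec = SplitSpec(cfg.outer_ratio, cfg.inner_ratio, cfg.stratified)
            tv_idx, _ = split_outer(dataset, spec, substream(cfg.seed, "outer_split"))
            mean = dataset.features[tv_idx].mean(axis=0)
            std = dataset.features[tv_idx].std(axis=0)
            std[std == 0] = 1.0
            scaler = (mean, std)
            dataset = LabeledFCDataset(
                features=(dataset.features - mean) / std,
                labels=dataset.labels,
                pair_map=dataset.pair_map,
                subject_ids=dataset.subject_ids,
            )
        history = run_evolution(dataset, cfg)
        return EvolutionResults(self, history, scaler=scaler, fitted_dataset=dataset)


class EvolutionResults:
    """Results of one evolutionary fit.

    Attributes
    ----------
    history : EvolutionHistory
        Per-generation records, optimal generation, stop reason.
    optimal_ensemble : WeightedEnsemble
        The ensemble of the accuracy-optimal generation.
    """

    def __init__(
        self,
        model: EvolvingSVMEnsemble,
        history: EvolutionHistory,
        scaler=None,
        fitted_dataset: LabeledFCDataset | None = None,
    ):
        self.model = model
        self.history = history
        self.config = history.config
        self.scaler = scaler
        self._dataset = fitted_dataset or model.dataset

    # -- core accessors -------------------------------------------------
    @property
    def optimal_generation(self) -> int:
        return self.history.optimal_generation

    @property
    def optimal_feature_set(self) -> np.ndarray:
        return self.history.optimal_feature_set

    @property
    def optimal_ensemble(self):
        ens = self.history.optimal_ensemble
        if ens is None:
            raise InvalidStateError("history carries no fitted ensemble")
        return ens

    @property
    def test_indices(self) -> np.ndarray:
        return self.history.test_indices

    @property
    def test_accuracy(self) -> float:
        """Held-out accuracy of the optimal generation."""
        return float(self.history.accuracies()[self.optimal_generation])

    # -- prediction ------------------------------------------------------
    def _as_features(self, X) -> np.ndarray:
        if X is None:
            return self._dataset.features
        if isinstance(X, ROITimeSeries):
            X = [X]
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], ROITimeSeries):
            pm = self._dataset.pair_map
            feats = np.vstack([compute_fc_vector(ts, pm) for ts in X])
        else:
            feats = np.asarray(X, dtype=float)
            if feats.ndim == 1:
                feats = feats[None, :]
        if self.scaler is not None:
            mean, std = self.scaler
            feats = (feats - mean) / std
        return feats

    def predict(self, X=None) -> np.ndarray:
        """Weighted-vote labels for ``X`` (feature matrix or time series);
        defaults to the fitted dataset's subjects."""
        # fitted features are already in the (possibly standardised) space
        feats = self._dataset.features if X is None else self._as_features(X)
        return predict_batch(self.optimal_ensemble, feats)

    def vote_weights(self, X=None) -> np.ndarray:
        """Per-sample summed vote weight for each label, columns (-1, +1)."""
        feats = self._dataset.features if X is None else self._as_features(X)
        return vote_totals(self.optimal_ensemble, feats)

    # -- evaluation ------------------------------------------------------
    def metric_report(self) -> MetricReport:
        """Accuracy/sensitivity/specificity of the optimal ensemble on the
        held-out test subjects."""
        idx = self.test_indices
        pred = predict_batch(self.optimal_ensemble, self._dataset.features[idx])
        return MetricReport.from_labels(
            self._dataset.labels[idx],
            pred,
            positive=self.config.positive_label,
            positive_name=self.config.positive_name,
            negative_name=self.config.negative_name,
        )

    # -- regions ---------------------------------------------------------
    def region_frequencies(self, region_table: RegionTable | None = None) -> RegionFrequencyTable:
        """Rank regions by how many optimal features touch them."""
        if region_table is None:
            R = self._dataset.region_count
            region_table = RegionTable(tuple(f"region-{i:02d}" for i in range(R)))
        return region_frequencies(
            self.optimal_feature_set, self._dataset.pair_map, region_table
        )

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        h = self.history
        cfg = self.config
        rep = self.metric_report()
        n_gen = len(h.records)
        opt = h.records[self.optimal_generation]
        lines = [
            "Evolutionary Weighted Random SVM Ensemble",
            "=" * 57,
            f"subjects: {self._dataset.n_subjects}   "
            f"regions: {self._dataset.region_count}   "
            f"FC features: {self._dataset.n_features}",
            f"members per generation: {cfg.n_members}   features per member: {cfg.m}",
            f"sigma: {cfg.sigma}   C: {cfg.C:g}   q: {cfg.q}   seed: {cfg.seed}",
            f"train+validation: {h.train_validation_indices.size}   "
            f"test: {h.test_indices.size}",
            f"generations run: {n_gen} (requested {cfg.n_evolutions + 1}); "
            f"{h.stop_reason}",
            "-" * 57,
            f"optimal generation: {self.optimal_generation}   "
            f"pool at that generation: {opt.pool_size_before}",
            f"optimal feature set ({cfg.optimal_set}): "
            f"{len(self.optimal_feature_set)} features",
            str(rep),
            "=" * 57,
        ]
        return "\n".join(lines)

    # -- persistence and plotting ----------------------------------------
    def save_ensemble(self, path, metadata: dict | None = None) -> None:
        """Write the optimal ensemble as self-describing JSON."""
        save_ensemble(
            self.optimal_ensemble,
            path,
            config=self.config.to_dict(),
            seed=self.config.seed,
            scaler=self.scaler,
            metadata=metadata,
        )

    def plot_history(self, ax=None):
        """Test accuracy and pool size per generation (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.history.to_frame()
        ax.plot(frame["generation"], frame["test_accuracy"], marker="o",
                label="test accuracy")
        ax.set_xlabel("evolution")
        ax.set_ylabel("test accuracy")
        ax.axvline(self.optimal_generation, ls="--", color="grey",
                   label=f"optimal ({self.optimal_generation})")
        ax2 = ax.twinx()
        ax2.plot(frame["generation"], frame["pool_size_before"], color="C1",
                 label="pool size")
        ax2.set_ylabel("feature-pool size")
        ax.legend(loc="lower left")
        return ax
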