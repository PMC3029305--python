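"""Replicate simulations of extreme array mapping: thresholds, power, precision.

A scenario fixes the population (type and size), the selection
intensity, the genetic model, the map, and the signal bank.  Each
replicate simulates a population, phenotypes it, selects the extreme
pools, assigns array signals by genotype class, smooths the
pool-difference trace, and records each chromosome's smoothed extremes.

Aggregation over replicates yields:

* **detection thresholds** — the nearest-rank 95th/99th percentiles of
  the pooled maxima and |minima| on chromosomes unlinked to any QTL,
  used as genome-scan significance cutoffs;
* **failure rate** — the percentage of replicates in which the linked
  chromosome's extreme (in the direction implied by the model's sign)
  does not exceed the 95% threshold;
* **positional confidence interval** — the width of the smallest window
  centred on the true locus that contains the peak position in the
  requested fraction of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_signal import (
    DEFAULT_BANK_PARAMS,
    SignalBank,
    assign_signals,
    make_synthetic_bank,
)
from .bsa_engine import LoessOperator, chromosome_extremes, pool_difference
from .genetic_models import (
    MODEL_PRESETS,
    GeneticMap,
    QTLLocus,
    QTLModel,
    default_map,
    genetic_value,
    marginal_allele_effect,
    model_preset,
    select_pools,
    simulate_phenotypes,
    simulate_population,
)

__all__ = [
    "ScenarioConfig",
    "SimulationSummary",
    "ThresholdSet",
    "nearest_rank_percentile",
    "run_batch",
    "detection_thresholds",
    "failure_rate",
    "confidence_interval",
    "table_report",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one batch of mapping simulations."""

    population_type: str
    population_size: int
    selection_fraction: float
    model: QTLModel
    map: GeneticMap = field(default_factory=default_map)
    bank: SignalBank | None = None
    bank_params: dict = field(default_factory=lambda: dict(DEFAULT_BANK_PARAMS))
    n_replicates: int = 500
    span: float = 0.25
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0 < self.selection_fraction <= 0.5:
            raise ValueError("selection_fraction must be in (0, 0.5]")
        for locus in self.model.loci:
            if locus.chrom not in self.map.lengths_cM:
                raise ValueError(f"model locus on unknown chromosome {locus.chrom!r}")

    @classmethod
    def from_preset(
        cls,
        preset: int,
        population_type: str,
        population_size: int,
        selection_fraction: float,
        **kwargs,
    ) -> "ScenarioConfig":
        return cls(
            population_type=population_type,
            population_size=population_size,
            selection_fraction=selection_fraction,
            model=model_preset(preset),
            label=f"model {preset}: {MODEL_PRESETS[preset]}",
            **kwargs,
        )

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScenarioConfig":
        """Build from a nested config mapping (the YAML file layout).

        Recognised keys: ``population.type``, ``population.size``,
        ``selection.fraction``, ``model.preset`` or ``model.loci`` (list
        of ``{chrom, pos_cM, a, d}``), ``model.env_sd``,
        ``model.reps_per_line``, ``map.lengths_cM`` (list or mapping),
        ``map.marker_spacing_cM``, ``bank.{mu_marker,sd_marker,
        sd_control}``, ``replicates``, ``span``, ``seed``.
        """
        pop = cfg.get("population", {})
        sel = cfg.get("selection", {})
        mdl = cfg.get("model", {})
        map_cfg = cfg.get("map", {})
        bank_cfg = cfg.get("bank", {})

        if "preset" in mdl:
            model = model_preset(
                int(mdl["preset"]),
                env_sd=float(mdl.get("env_sd", 1.0)),
                reps_per_line=int(mdl.get("reps_per_line", 3)),
            )
        else:
            loci = tuple(
                QTLLocus(
                    chrom=str(l["chrom"]),
                    pos_cM=float(l["pos_cM"]),
                    a=float(l.get("a", 0.0)),
                    d=float(l.get("d", 0.0)),
                )
                for l in mdl.get("loci", [])
            )
            epistasis = mdl.get("epistasis")
            model = QTLModel(
                loci=loci,
                epistasis=None if epistasis is None else np.asarray(epistasis, dtype=float),
                env_sd=float(mdl.get("env_sd", 1.0)),
                reps_per_line=int(mdl.get("reps_per_line", 3)),
            )

        lengths = map_cfg.get("lengths_cM")
        spacing = float(map_cfg.get("marker_spacing_cM", 0.5))
        if lengths is None:
            gmap = default_map(spacing)
        else:
            if isinstance(lengths, (list, tuple)):
                lengths = {str(i + 1): float(v) for i, v in enumerate(lengths)}
            else:
                lengths = {str(k): float(v) for k, v in lengths.items()}
            gmap = GeneticMap.uniform(lengths, spacing)

        bank_params = dict(DEFAULT_BANK_PARAMS)
        bank_params.update({k: float(v) for k, v in bank_cfg.items()})

        return cls(
            population_type=str(pop.get("type", "F2")),
            population_size=int(pop.get("size", 200)),
            selection_fraction=float(sel.get("fraction", 0.10)),
            model=model,
            map=gmap,
            bank_params=bank_params,
            n_replicates=int(cfg.get("replicates", 500)),
            span=float(cfg.get("span", 0.25)),
            seed=int(cfg.get("seed", 0)),
            label=str(cfg.get("label", "")),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SimulationSummary:
    """Per-replicate per-chromosome smoothed-trace extremes for one scenario."""

    config: ScenarioConfig
    chromosome_names: tuple[str, ...]
    max_values: np.ndarray  # replicates x chromosomes
    max_positions: np.ndarray
    min_values: np.ndarray
    min_positions: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.max_values.shape[0]

    @property
    def linked_chromosomes(self) -> set[str]:
        return self.config.model.linked_chromosomes

    @property
    def unlinked_chromosomes(self) -> list[str]:
        return [c for c in self.chromosome_names if c not in self.linked_chromosomes]

    def chrom_index(self, chrom: str) -> int:
        return self.chromosome_names.index(chrom)


@dataclass(frozen=True)
class ThresholdSet:
    """Genome-scan detection cutoffs in signal units."""

    threshold_95: float
    threshold_99: float

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_95 <= self.threshold_99:
            raise ValueError("need threshold_99 >= threshold_95 >= 0")


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ``ceil(q * n)``-th smallest value."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty value list")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    rank = math.ceil(q * values.size)
    return float(values[rank - 1])


def run_batch(config: ScenarioConfig) -> SimulationSummary:
    """Run every replicate of a scenario and collect chromosome extremes.

    Deterministic under the scenario's master seed: a seed sequence
    derived from it provides one stream per replicate (plus one for the
    synthetic bank when no bank is supplied).
    """
    ss = np.random.SeedSequence(config.seed)
    bank_ss, *rep_ss = ss.spawn(config.n_replicates + 1)
    bank = config.bank
    if bank is None:
        bank = make_synthetic_bank(
            seed=np.random.default_rng(bank_ss), **config.bank_params
        )

    op = LoessOperator(config.map, span=config.span)
    chrom_names = tuple(config.map.chromosome_names)
    shape = (config.n_replicates, len(chrom_names))
    max_v, max_p = np.empty(shape), np.empty(shape)
    min_v, min_p = np.empty(shape), np.empty(shape)

    for rep, child in enumerate(rep_ss):
        rng = np.random.default_rng(child)
        genotypes = simulate_population(
            config.map, config.population_type, config.population_size, rng
        )
        values = genetic_value(genotypes, config.model)
        phenotypes = simulate_phenotypes(values, config.model, rng)
        pools = select_pools(phenotypes, config.selection_fraction)
        # only the pooled individuals are hybridized
        high = assign_signals(genotypes.subset(pools.high_pool), bank, rng)
        low = assign_signals(genotypes.subset(pools.low_pool), bank, rng)
        raw = pool_difference(high, low)
        record = chromosome_extremes(op.trace(raw))
        for c, name in enumerate(chrom_names):
            ext = record.chromosomes[name]
            max_v[rep, c], max_p[rep, c] = ext.max_value, ext.max_position
            min_v[rep, c], min_p[rep, c] = ext.min_value, ext.min_position

    return SimulationSummary(
        config=config,
        chromosome_names=chrom_names,
        max_values=max_v,
        max_positions=max_p,
        min_values=min_v,
        min_positions=min_p,
    )


def detection_thresholds(summary: SimulationSummary) -> ThresholdSet:
    """Pool unlinked-chromosome maxima and |minima|; take the 95th/99th
    nearest-rank percentiles."""
    unlinked = summary.unlinked_chromosomes
    if not unlinked:
        raise ValueError("no unlinked chromosomes to build thresholds from")
    cols = [summary.chrom_index(c) for c in unlinked]
    pooled = np.concatenate(
        [summary.max_values[:, cols].ravel(), np.abs(summary.min_values[:, cols]).ravel()]
    )
    return ThresholdSet(
        threshold_95=nearest_rank_percentile(pooled, 0.95),
        threshold_99=nearest_rank_percentile(pooled, 0.99),
    )


def _locus_direction(summary: SimulationSummary, locus_index: int) -> int:
    sign = marginal_allele_effect(
        summary.config.model, locus_index, summary.config.population_type
    )
    return -1 if sign < 0 else 1


def _linked_extremes(
    summary: SimulationSummary, locus_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed extreme values and their positions on the locus chromosome,
    in the direction the model's reference allele pushes the signal."""
    locus = summary.config.model.loci[locus_index]
    if locus.chrom not in summary.linked_chromosomes:
        raise ValueError(f"locus chromosome {locus.chrom!r} is not linked")
    c = summary.chrom_index(locus.chrom)
    if _locus_direction(summary, locus_index) >= 0:
        return summary.max_values[:, c], summary.max_positions[:, c]
    return -summary.min_values[:, c], summary.min_positions[:, c]


def failure_rate(
    summary: SimulationSummary, thresholds: ThresholdSet, locus_index: int = 0
) -> float:
    """Percentage of replicates whose linked-chromosome extreme (in the
    expected direction) does not exceed the 95% threshold."""
    extremes, _ = _linked_extremes(summary, locus_index)
    return float(100.0 * np.mean(extremes <= thresholds.threshold_95))


def confidence_interval(
    summary: SimulationSummary, locus_index: int = 0, coverage: float = 0.95
) -> float:
    """Width (cM) of the smallest locus-centred window containing the
    peak position in at least ``coverage`` of the replicates.

    The window is intersected with the chromosome, so the reported
    width never exceeds the chromosome length.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if summary.n_replicates < 1:
        raise ValueError("empty summary")
    locus = summary.config.model.loci[locus_index]
    _, positions = _linked_extremes(summary, locus_index)
    gmap = summary.config.map
    true_pos = float(
        gmap.markers[locus.chrom][
            np.argmin(np.abs(gmap.markers[locus.chrom] - locus.pos_cM))
        ]
    )
    half_width = nearest_rank_percentile(np.abs(positions - true_pos), coverage)
    length = gmap.lengths_cM[locus.chrom]
    return float(min(true_pos + half_width, length) - max(true_pos - half_width, 0.0))


def table_report(configs: list[ScenarioConfig], coverage: float = 0.95) -> pd.DataFrame:
    """Run a list of scenarios and aggregate a mapping report.

    Thresholds are averaged across genetic models within each
    (population type, size, selection fraction) group — they are
    approximately equal within a group since unlinked chromosomes carry
    no QTL signal — then failure rates and confidence-interval widths
    are reported per linked locus against the group-averaged thresholds.

    Columns: model, effect, chromosome, position_cM, population,
    selection, threshold95, threshold99, failure_pct, ci95_cM.
    """
    if not configs:
        raise ValueError("no scenarios supplied")
    summaries = [run_batch(cfg) for cfg in configs]
    raw_thresholds = [detection_thresholds(s) for s in summaries]

    groups: dict[tuple, list[int]] = {}
    for i, cfg in enumerate(configs):
        key = (cfg.population_type, cfg.population_size, cfg.selection_fraction)
        groups.setdefault(key, []).append(i)
    averaged = {
        key: ThresholdSet(
            threshold_95=float(np.mean([raw_thresholds[i].threshold_95 for i in idx])),
            threshold_99=float(np.mean([raw_thresholds[i].threshold_99 for i in idx])),
        )
        for key, idx in groups.items()
    }

    rows = []
    for cfg, summary in zip(configs, summaries):
        key = (cfg.population_type, cfg.population_size, cfg.selection_fraction)
        thr = averaged[key]
        for i, locus in enumerate(cfg.model.loci):
            rows.append(
                {
                    "model": cfg.label or "custom",
                    "effect": f"a={locus.a:g}, d={locus.d:g}",
                    "chromosome": locus.chrom,
                    "position_cM": locus.pos_cM,
                    "population": f"{cfg.population_size} {cfg.population_type}",
                    "selection": cfg.selection_fraction,
                    "threshold95": thr.threshold_95,
                    "threshold99": thr.threshold_99,
                    "failure_pct": failure_rate(summary, thr, i),
                    "ci95_cM": confidence_interval(summary, i, coverage),
                }
            )
    return pd.DataFrame(rows)
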