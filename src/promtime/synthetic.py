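"""Synthetic ChEMBL-like longitudinal activity datasets with known ground truth.

The generator emulates the statistical shape of a public bioactivity
database accumulating records over decades: annual compound debuts grow
slowly for thirty years and then steeply after a breakpoint year; the
distribution of per-compound final target counts is heavily concentrated at
one target; and record-level confidence attributes (assay relationship
type, confidence score, target type, organism, measurement type/relation,
comments) are drawn from a configurable mix so both confidence tiers are
exercised.  Every run is deterministic given the seed, and the emitted
Dataset is paired with a GroundTruth recording the per-compound target sets
and debut years it was built from.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from promtime.records import CANONICAL_COLUMNS, Dataset

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """A generator configuration field is invalid; the message names it."""


def _default_promiscuity_distribution() -> dict[int, float]:
    # mass concentrated at a single target, thin tail of multi-target compounds
    return {1: 0.985, 2: 0.006, 3: 0.003, 4: 0.002, 5: 0.001,
            10: 0.001, 20: 0.001, 55: 0.001}


def _default_confidence_mix() -> dict[str, dict]:
    # joint mass of fully high-confidence-conforming records is ~0.3
    return {
        "relationship_type": {"D": 0.85, "H": 0.10, "N": 0.05},
        "confidence_score": {9: 0.80, 8: 0.10, 7: 0.05, 5: 0.05},
        "target_type": {"SINGLE PROTEIN": 0.80, "PROTEIN COMPLEX": 0.12, "CELL-LINE": 0.08},
        "organism": {"Homo sapiens": 0.85, "Rattus norvegicus": 0.10, "Mus musculus": 0.05},
        "measurement_type": {"Ki": 0.40, "IC50": 0.45, "EC50": 0.10, "Potency": 0.05},
        "measurement_relation": {"=": 0.85, ">": 0.08, "<": 0.05, "~": 0.02},
        "activity_comment": {"": 0.90, "Active": 0.05, "inactive": 0.03,
                             "Not Active": 0.01, "Inconclusive": 0.01},
    }


def _default_records_per_pair() -> dict[int, float]:
    return {1: 0.80, 2: 0.15, 3: 0.05}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    Attributes
    ----------
    year_range
        Inclusive (start, end) release years; the end year is the horizon.
    n_compounds
        Number of compounds to emit.
    growth_model
        ``"linear"`` (debut weight grows linearly across the whole range)
        or ``"piecewise_exponential"`` (linear ramp until
        ``breakpoint_year``, then a jump and exponential growth).
    breakpoint_year, pre_break_ramp, post_break_jump, post_break_rate
        Shape of the piecewise model: debut weight 1 + ramp*(y - start)
        before the breakpoint, then jump * rate**(y - breakpoint) times the
        breakpoint weight.
    promiscuity_distribution
        Probability over a compound's final distinct-target count.
    debut_multiplicity
        Probability that a multi-target compound receives its full target
        set already in its debut year (promiscuity gain 0 despite >1
        target); otherwise it debuts with one target and accretes the rest
        in strictly later years, sampled uniformly up to the horizon.
    confidence_mix
        Per-attribute categorical distributions.  Target type and organism
        are drawn once per target, relationship type and confidence score
        once per assay, the rest per record.
    records_per_pair
        Distribution of repeated measurements per compound--target pair;
        repeats fall in uniform years between the pair's first year and the
        horizon.
    value_missing_rate
        Probability a record carries no numeric measurement value.
    seed
        Master seed; all randomness flows from one generator stream.
    """

    year_range: tuple[int, int] = (1976, 2014)
    n_compounds: int = 1000
    growth_model: str = "piecewise_exponential"
    breakpoint_year: int = 2006
    pre_break_ramp: float = 0.25
    post_break_jump: float = 3.0
    post_break_rate: float = 1.15
    promiscuity_distribution: dict[int, float] = field(
        default_factory=_default_promiscuity_distribution)
    debut_multiplicity: float = 0.0
    confidence_mix: dict[str, dict] = field(default_factory=_default_confidence_mix)
    records_per_pair: dict[int, float] = field(default_factory=_default_records_per_pair)
    value_missing_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        start, end = self.year_range
        if start >= end:
            raise ConfigError(f"year_range: start {start} must precede end {end}")
        if self.n_compounds < 1:
            raise ConfigError(f"n_compounds: must be >= 1, got {self.n_compounds}")
        if self.growth_model not in ("linear", "piecewise_exponential"):
            raise ConfigError(f"growth_model: unknown model {self.growth_model!r}")
        if not (0.0 <= self.debut_multiplicity <= 1.0):
            raise ConfigError("debut_multiplicity: must be a probability in [0, 1]")
        if not (0.0 <= self.value_missing_rate <= 1.0):
            raise ConfigError("value_missing_rate: must be a probability in [0, 1]")
        self._check_dist("promiscuity_distribution", self.promiscuity_distribution)
        if any(k < 1 for k in self.promiscuity_distribution):
            raise ConfigError("promiscuity_distribution: target counts must be >= 1")
        self._check_dist("records_per_pair", self.records_per_pair)
        if any(k < 1 for k in self.records_per_pair):
            raise ConfigError("records_per_pair: counts must be >= 1")
        for attr, dist in self.confidence_mix.items():
            self._check_dist(f"confidence_mix[{attr}]", dist)

    @staticmethod
    def _check_dist(name: str, dist: dict) -> None:
        if not dist:
            raise ConfigError(f"{name}: empty distribution")
        if any(p < 0 for p in dist.values()):
            raise ConfigError(f"{name}: negative probability")
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=_PROB_TOL):
            raise ConfigError(f"{name}: probabilities sum to {total}, not 1")


@dataclass
class GroundTruth:
    """What the generator actually built, for checking pipeline recovery.

    ``final_targets`` and ``first_year`` come straight from the sampling
    decisions; ``new_entities_by_year`` tallies first-appearance years of
    the emitted identifiers (and record counts for activities).
    """

    final_targets: dict[str, frozenset]
    first_year: dict[str, int]
    new_entities_by_year: dict[str, dict[int, int]]

    @property
    def constant_promiscuity_fraction(self) -> float:
        """True fraction of compounds whose degree never grows after debut."""
        n_constant = sum(
            1 for cid, targets in self.final_targets.items()
            if len(targets) == self._debut_size(cid)
        )
        return n_constant / len(self.final_targets)

    def _debut_size(self, cid: str) -> int:
        return self._debut_sizes[cid]

    # populated by generate(); kept out of the dataclass signature
    _debut_sizes: dict[str, int] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "final_targets": {c: sorted(t) for c, t in self.final_targets.items()},
            "first_year": self.first_year,
            "debut_target_counts": self._debut_sizes,
            "new_entities_by_year": {
                kind: {str(y): n for y, n in sorted(counts.items())}
                for kind, counts in self.new_entities_by_year.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _debut_weights(config: GeneratorConfig) -> np.ndarray:
    start, end = config.year_range
    years = np.arange(start, end + 1)
    ramp = 1.0 + config.pre_break_ramp * (years - start)
    if config.growth_model == "linear":
        w = ramp
    else:
        w = ramp.copy()
        post = years > config.breakpoint_year
        w_break = 1.0 + config.pre_break_ramp * (config.breakpoint_year - start)
        w[post] = (w_break * config.post_break_jump
                   * config.post_break_rate ** (years[post] - config.breakpoint_year))
    return w / w.sum()


def _sampler(dist: dict, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()

    def draw():
        return keys[rng.choice(len(keys), p=probs)]

    return draw


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Emit a synthetic Dataset and the GroundTruth it was built from.

    Deterministic given ``config.seed``.  Each compound receives a debut
    year from the growth model and a final target set sized from the
    promiscuity distribution; multi-target compounds either debut with the
    full set (probability ``debut_multiplicity``) or accrete targets in
    strictly later uniform years.  Per-record confidence attributes follow
    ``confidence_mix``, with target-level and assay-level attributes held
    consistent per identifier.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start, end = config.year_range
    n = config.n_compounds

    debut_years = rng.choice(np.arange(start, end + 1), size=n, p=_debut_weights(config))

    draw_k = _sampler(config.promiscuity_distribution, rng)
    draw_repeats = _sampler(config.records_per_pair, rng)
    mix = config.confidence_mix
    draw_ttype = _sampler(mix["target_type"], rng)
    draw_organism = _sampler(mix["organism"], rng)
    draw_rel = _sampler(mix["relationship_type"], rng)
    draw_score = _sampler(mix["confidence_score"], rng)
    draw_mtype = _sampler(mix["measurement_type"], rng)
    draw_mrel = _sampler(mix["measurement_relation"], rng)
    draw_comment = _sampler(mix["activity_comment"], rng)

    max_k = max(config.promiscuity_distribution)
    n_targets_pool = max(2 * max_k, 10 + n // 4)
    target_attrs: dict[str, tuple[str, str]] = {}
    assay_attrs: dict[str, tuple[str, int]] = {}
    n_assay_pool = max(4, n // 3)

    rows: list[tuple] = []
    final_targets: dict[str, frozenset] = {}
    first_year: dict[str, int] = {}
    debut_sizes: dict[str, int] = {}

    for i in range(n):
        cid = f"CPD{i:06d}"
        k = int(draw_k())
        debut = int(debut_years[i])
        full_debut = k == 1 or rng.random() < config.debut_multiplicity
        if not full_debut and debut >= end:
            debut = end - 1  # leave room for accretion strictly after debut
        target_idx = rng.choice(n_targets_pool, size=k, replace=False)
        tids = [f"TGT{int(t):05d}" for t in np.sort(target_idx)]
        if full_debut:
            pair_years = {tid: debut for tid in tids}
        else:
            later = rng.integers(debut + 1, end + 1, size=k - 1)
            pair_years = {tids[0]: debut}
            pair_years.update(zip(tids[1:], later.tolist()))
        final_targets[cid] = frozenset(tids)
        first_year[cid] = debut
        debut_sizes[cid] = sum(1 for y in pair_years.values() if y == debut)

        for tid, pair_year in pair_years.items():
            if tid not in target_attrs:
                target_attrs[tid] = (draw_ttype(), draw_organism())
            ttype, organism = target_attrs[tid]
            n_rec = int(draw_repeats())
            rec_years = [int(pair_year)]
            if n_rec > 1:
                rec_years += rng.integers(pair_year, end + 1, size=n_rec - 1).tolist()
            for year in rec_years:
                aid = f"ASY{int(rng.integers(0, n_assay_pool)):05d}"
                if aid not in assay_attrs:
                    assay_attrs[aid] = (draw_rel(), int(draw_score()))
                rel, score = assay_attrs[aid]
                value = (
                    np.nan if rng.random() < config.value_missing_rate
                    else float(np.round(np.exp(rng.normal(np.log(100.0), 2.0)), 4))
                )
                rows.append((
                    cid, tid, ttype, organism, aid, rel, score,
                    draw_mtype(), draw_mrel(), draw_comment(), int(year), value,
                ))

    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    # repeated measurements can collide on every field; emit each record once
    frame = frame.drop_duplicates(ignore_index=True)
    dataset = Dataset(frame, provenance=f"synthetic(seed={config.seed})", validate=False)

    new_by_year: dict[str, dict[int, int]] = {}
    for kind, column in (("compounds", "compound_id"), ("targets", "target_id"),
                         ("assays", "assay_id")):
        firsts = frame.groupby(column, observed=True)["release_year"].min()
        new_by_year[kind] = {int(y): int(c) for y, c in firsts.value_counts().items()}
    new_by_year["activities"] = {
        int(y): int(c) for y, c in frame["release_year"].value_counts().items()
    }

    truth = GroundTruth(
        final_targets=final_targets,
        first_year=first_year,
        new_entities_by_year=new_by_year,
        _debut_sizes=debut_sizes,
    )
    return dataset, truth


def _conforming_record(cid: str, tid: str, aid: str, year: int, value: float,
                       mtype: str = "Ki") -> tuple:
    return (cid, tid, "SINGLE PROTEIN", "Homo sapiens", aid, "D", 9,
            mtype, "=", "", year, value)


def worked_example_fixture() -> Dataset:
    """One compound active against target A in 1990, B and C in 2000, D in 2005.

    Its cumulative promiscuity degree runs 1 (1990), 3 (2000), 4 (2005).
    All four records conform to the high-confidence tier.
    """
    rows = [
        _conforming_record("CPD-EX", "TGT-A", "ASY-1", 1990, 120.0),
        _conforming_record("CPD-EX", "TGT-B", "ASY-2", 2000, 85.0),
        _conforming_record("CPD-EX", "TGT-C", "ASY-3", 2000, 430.0, "IC50"),
        _conforming_record("CPD-EX", "TGT-D", "ASY-4", 2005, 15.0, "IC50"),
    ]
    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return Dataset(frame, provenance="worked-example")


def constant_promiscuity_fixture(n_targets: int, first_year: int) -> Dataset:
    """One compound debuting with ``n_targets`` targets and never gaining more.

    Models the common case of a compound reported once against a fixed
    target panel whose promiscuity degree then stays flat (gain 0) however
    long it remains in the database.
    """
    if n_targets < 1:
        raise ConfigError(f"n_targets: must be >= 1, got {n_targets}")
    rows = [
        _conforming_record("CPD-CONST", f"TGT-{j:03d}", f"ASY-{j:03d}",
                           first_year, 100.0 + j)
        for j in range(n_targets)
    ]
    frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return Dataset(frame, provenance=f"constant-promiscuity({n_targets},{first_year})")
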