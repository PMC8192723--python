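"""Ground-truth-labelled synthetic serial-transfer invasion experiments.

The generator emulates the structure of a whole-community invasion study in
laboratory anaerobic digesters: two source communities that share most ASVs
(a low-producer resident, LP, and a high-producer invader, HP), volumetric
invasion of LP replicates at four doses spanning three orders of magnitude,
weekly feeding modelled as Wright-Fisher multinomial bottlenecks, endpoint
16S sequencing at realistic read depths, and weekly cumulative biogas whose
rate steps up only when a set of functionally key invader taxa establishes.

Model mechanics
---------------
* Source profiles: per-community lognormal relative abundances over shared
  and community-unique ASVs.
* Invasion: volumetric mixing, ``(1-d) * LP + d * HP``.
* Dynamics: one multinomial bottleneck of ``bottleneck_N`` cells per weekly
  feeding. In invaded communities HP-origin unique taxa carry a relative
  fitness ``1+s`` (the invader community is better adapted to the substrate),
  jittered per replicate on the log scale; pure communities transfer
  neutrally, being at their own competitive equilibrium.
* Establishment threshold: an HP-origin taxon below frequency
  ``establishment_freq`` grows at ``sub_establishment_fitness`` instead of
  ``1+s`` (positive density dependence / priority effect of the resident).
  This is what makes invader taxa below a dose-dependent abundance cutoff
  fail deterministically, giving the tipping-point structure of the data.
* Gas: weekly rate ``gas_base_rate`` for LP-like metabolism and
  ``gas_hp_rate`` for the pure invader; an invaded community switches, after
  a lag, to ``gas_boost_rate`` (a catch-up rate, consuming the backlog of
  undigested feed) if and only if at least ``key_taxa_k`` of the planted key
  taxa are present at the endpoint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .phylo import PhyloTree, TreeNode
from .tables_io import (
    AsvCountTable,
    GasSeries,
    SampleMetadata,
    TREATMENT_DOSE,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedStudy",
    "generate_sources",
    "mix",
    "transfer_dynamics",
    "sample_reads",
    "gas_series",
    "simulate_study",
    "random_coalescent_tree",
]

ORIGIN_LP = "LP_only"
ORIGIN_HP = "HP_only"
ORIGIN_SHARED = "shared"


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    # community composition
    n_shared: int = 150
    n_lp_unique: int = 80
    n_hp_unique: int = 80
    abundance_sigma: float = 2.5  # lognormal shape of relative abundances

    # experimental design
    doses: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)  # volume fractions
    replicates: int = 5
    n_transfers_pre: int = 2  # weekly feedings before invasion
    n_transfers_post: int = 6  # weekly feedings after invasion
    drop_hp_sample: bool = True  # one pure-HP endpoint failed to sequence

    # dynamics
    bottleneck_N: int = 100_000  # cells surviving each weekly bottleneck
    invader_fitness_s: float = 16.0  # relative advantage of HP-unique taxa
    fitness_rep_sigma: float = 0.5  # per-replicate jitter, sd of ln(1+s)
    establishment_freq: float = 1e-6  # Allee threshold on community frequency
    sub_establishment_fitness: float = 0.0  # growth weight below the threshold

    # sequencing
    read_depth: int | None = None  # None -> uniform in [350_000, 500_000]
    read_depth_range: tuple[int, int] = (350_000, 500_000)

    # key taxa and gas readout
    key_taxa_k: int = 5  # how many key taxa must establish for the boost
    n_key_taxa: int = 8  # size of the planted key-taxon set
    key_taxa_rare_bias: bool = True  # plant key taxa at low (band) abundance
    key_band_margin: float = 2.0  # safety factor inside the tipping band
    gas_base_rate: float = 200.0  # mL/week, LP-like metabolism
    gas_hp_rate: float = 320.0  # mL/week, pure invader community
    gas_boost_rate: float = 680.0  # mL/week post-lag catch-up in invaded
    gas_lag_weeks: int = 4
    gas_noise_sd: float = 20.0  # mL/week additive noise on increments

    seed: int = 0

    def __post_init__(self):
        if not all(0 < d < 1 for d in self.doses):
            raise ConfigurationError("doses must lie in (0, 1)")
        if self.bottleneck_N < 1:
            raise ConfigurationError("bottleneck_N must be >= 1")
        if self.abundance_sigma < 0:
            raise ConfigurationError("abundance_sigma must be >= 0")
        if self.invader_fitness_s < -1:
            raise ConfigurationError("invader_fitness_s must be >= -1")
        if self.key_taxa_k > self.n_key_taxa:
            raise ConfigurationError("key_taxa_k cannot exceed n_key_taxa")
        if self.n_key_taxa > self.n_hp_unique:
            raise ConfigurationError("n_key_taxa cannot exceed n_hp_unique")
        if self.read_depth is not None and self.read_depth < 1:
            raise ConfigurationError("read_depth must be >= 1")
        self.doses = tuple(sorted(self.doses, reverse=True))

    @property
    def n_asvs(self) -> int:
        return self.n_shared + self.n_lp_unique + self.n_hp_unique

    @property
    def n_weeks(self) -> int:
        return self.n_transfers_pre + self.n_transfers_post

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["doses"] = list(self.doses)
        data["read_depth_range"] = list(self.read_depth_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "doses" in data:
            data["doses"] = tuple(data["doses"])
        if "read_depth_range" in data:
            data["read_depth_range"] = tuple(data["read_depth_range"])
        return cls(**data)


@dataclass
class SimTruth:
    """The generator's ground truth; the oracle for attribution accuracy."""

    asv_ids: list[str]
    origin: dict[str, str]  # asv_id -> LP_only | HP_only | shared
    key_taxa: list[str] = field(default_factory=list)
    sample_dose: dict[str, float] = field(default_factory=dict)
    invader_trajectory: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        labels = set(self.origin.values())
        if not labels <= {ORIGIN_LP, ORIGIN_HP, ORIGIN_SHARED}:
            raise ValidationError(f"unknown origin label(s): {labels}")
        if set(self.origin) != set(self.asv_ids):
            raise ValidationError("origin map must cover exactly the simulated ASVs")
        hp = {a for a, o in self.origin.items() if o == ORIGIN_HP}
        if not set(self.key_taxa) <= hp:
            raise ValidationError("key taxa must be HP-unique ASVs")

    def origin_array(self) -> np.ndarray:
        return np.array([self.origin[a] for a in self.asv_ids])

    def hp_mask(self) -> np.ndarray:
        return self.origin_array() == ORIGIN_HP

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "asv_ids": self.asv_ids,
                    "origin": self.origin,
                    "key_taxa": self.key_taxa,
                    "sample_dose": self.sample_dose,
                    "invader_trajectory": self.invader_trajectory,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class SimulatedStudy:
    table: AsvCountTable
    metadata: SampleMetadata
    tree: PhyloTree
    gas: GasSeries
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# deterministic substreams


def _stable_hash(*parts: str) -> int:
    digest = hashlib.blake2b(":".join(parts).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def sample_rng(seed: int, treatment: str, replicate: int) -> np.random.Generator:
    """Per-sample random stream derived by stable hashing of (treatment,
    replicate), so adding samples never perturbs existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, _stable_hash(treatment, str(replicate))])
    )


# ---------------------------------------------------------------------------
# sources


def _lognormal_weights(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def generate_sources(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Draw the two source community profiles and their ground truth.

    Returns relative-abundance vectors over the full ASV panel (shared ASVs
    first, then LP-unique, then HP-unique) and a :class:`SimTruth` holding
    the origin partition and the planted key-taxon set.

    Key taxa are HP-unique taxa placed (when ``key_taxa_rare_bias`` is on,
    the default) inside the "tipping band" of abundances that clear the
    establishment threshold at the second-highest dose but not at the next
    dose down - the taxa whose presence separates high- from low-dose
    invasions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_asvs
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    shared = slice(0, config.n_shared)
    lp_u = slice(config.n_shared, config.n_shared + config.n_lp_unique)
    hp_u = slice(config.n_shared + config.n_lp_unique, n)

    lp = np.zeros(n)
    hp = np.zeros(n)
    lp[shared] = _lognormal_weights(rng, config.n_shared, config.abundance_sigma)
    lp[lp_u] = _lognormal_weights(rng, config.n_lp_unique, config.abundance_sigma)
    hp[shared] = _lognormal_weights(rng, config.n_shared, config.abundance_sigma)
    hp[hp_u] = _lognormal_weights(rng, config.n_hp_unique, config.abundance_sigma)
    lp /= lp.sum()
    hp /= hp.sum()

    origin = {}
    for i, asv in enumerate(asv_ids):
        if i < config.n_shared:
            origin[asv] = ORIGIN_SHARED
        elif i < config.n_shared + config.n_lp_unique:
            origin[asv] = ORIGIN_LP
        else:
            origin[asv] = ORIGIN_HP

    hp_indices = np.arange(hp_u.start, hp_u.stop)
    key_idx = rng.choice(hp_indices, size=config.n_key_taxa, replace=False)
    if config.key_taxa_rare_bias and config.n_key_taxa > 0 and len(config.doses) >= 3:
        doses = config.doses  # sorted descending
        lo = config.key_band_margin * config.establishment_freq / doses[1]
        hi = config.establishment_freq / (config.key_band_margin * doses[2])
        if lo < hi:
            targets = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_key_taxa))
            others = np.ones(n, dtype=bool)
            others[key_idx] = False
            hp[key_idx] = 0.0
            hp[others] *= (1.0 - targets.sum()) / hp[others].sum()
            hp[key_idx] = targets

    truth = SimTruth(
        asv_ids=asv_ids,
        origin=origin,
        key_taxa=[asv_ids[i] for i in sorted(key_idx)],
    )
    return lp, hp, truth


# ---------------------------------------------------------------------------
# dynamics


def mix(lp_profile: np.ndarray, hp_profile: np.ndarray, dose: float) -> np.ndarray:
    """Volumetric invasion: ``(1-dose) * lp + dose * hp``."""
    if not 0 < dose < 1:
        raise ConfigurationError(f"dose must lie in (0, 1), got {dose}")
    return (1.0 - dose) * np.asarray(lp_profile) + dose * np.asarray(hp_profile)


def _fitness_weights(
    profile: np.ndarray, hp_mask: np.ndarray, config: SimConfig, s: float
) -> np.ndarray:
    w = np.ones_like(profile)
    above = hp_mask & (profile >= config.establishment_freq)
    below = hp_mask & (profile > 0) & (profile < config.establishment_freq)
    w[above] = 1.0 + s
    w[below] = config.sub_establishment_fitness
    return w


def transfer_dynamics(
    profile: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    n_transfers: int,
    rng: np.random.Generator,
    *,
    selection: bool = True,
    s: float | None = None,
    deterministic: bool = False,
    trajectory: list[float] | None = None,
) -> np.ndarray:
    """Iterate weekly serial-transfer bottlenecks.

    Each transfer reweights taxon frequencies by relative fitness and then
    resamples ``bottleneck_N`` cells multinomially (taxa hitting zero stay
    zero; there is no migration). ``selection=False`` gives neutral
    Wright-Fisher dynamics (pure communities); ``deterministic=True`` takes
    the infinite-population limit and skips the multinomial resampling.

    ``s`` overrides ``config.invader_fitness_s`` (used for the per-replicate
    fitness jitter). When ``trajectory`` is a list, the total HP-origin
    frequency after every transfer is appended to it.
    """
    p = np.asarray(profile, dtype=float).copy()
    if not np.isclose(p.sum(), 1.0):
        raise ValidationError("profile must sum to 1")
    hp_mask = truth.hp_mask()
    s_eff = config.invader_fitness_s if s is None else s
    for _ in range(n_transfers):
        if selection:
            w = _fitness_weights(p, hp_mask, config, s_eff)
            q = p * w
        else:
            q = p.copy()
        total = q.sum()
        if total == 0:
            raise ValidationError("community went extinct (all weights zero)")
        q /= total
        if deterministic:
            p = q
        else:
            counts = rng.multinomial(config.bottleneck_N, q)
            p = counts / config.bottleneck_N
        if trajectory is not None:
            trajectory.append(float(p[hp_mask].sum()))
    return p


def sample_reads(
    profile: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequencing as multinomial read sampling at the given depth."""
    p = np.asarray(profile, dtype=float)
    return rng.multinomial(int(depth), p / p.sum())


# ---------------------------------------------------------------------------
# gas readout


def gas_series(
    endpoint_profile: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    invasion_week: int,
    *,
    treatment: str = "invaded",
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Weekly cumulative gas rows for one sample.

    Pure HP runs at ``gas_hp_rate`` throughout; pure LP at ``gas_base_rate``.
    An invaded community runs at the base rate and switches to
    ``gas_boost_rate`` from week ``invasion_week + gas_lag_weeks + 1`` onward
    iff at least ``key_taxa_k`` of the key taxa are present (nonzero) in the
    endpoint profile. Optional Gaussian noise is added to weekly increments
    (clipped at zero so cumulative values stay non-decreasing).
    """
    idx = {a: i for i, a in enumerate(truth.asv_ids)}
    n_present = sum(
        1 for a in truth.key_taxa if endpoint_profile[idx[a]] > 0
    )
    boosted = n_present >= config.key_taxa_k
    rows = []
    cumulative = 0.0
    for week in range(1, config.n_weeks + 1):
        if treatment == "HP":
            rate = config.gas_hp_rate
        elif treatment == "LP":
            rate = config.gas_base_rate
        else:
            post_lag = week > invasion_week + config.gas_lag_weeks
            rate = config.gas_boost_rate if (boosted and post_lag) else config.gas_base_rate
        if rng is not None and config.gas_noise_sd > 0:
            rate = max(rate + rng.normal(0.0, config.gas_noise_sd), 0.0)
        cumulative += rate
        rows.append(
            {"sample_id": sample_id, "week": week, "cumulative_gas_ml": cumulative}
        )
    return rows


# ---------------------------------------------------------------------------
# tree


def random_coalescent_tree(
    asv_ids: list[str], rng: np.random.Generator
) -> PhyloTree:
    """Random topology by iterative pairwise joining, Exp(1) branch lengths.

    UniFrac only needs a valid rooted tree over the ASV panel; no attempt is
    made to model real 16S divergence.
    """
    lineages = [TreeNode(name=a, length=float(rng.exponential(1.0))) for a in asv_ids]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        right = lineages.pop(j)
        left = lineages.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# full study


def _treatment_samples(config: SimConfig) -> list[tuple[str, int, float]]:
    """(treatment, replicate, dose) in fixed order; dose 0 for LP, 1 for HP."""
    dose_labels = {
        0.1: "D10",
        0.01: "D1",
        0.001: "D0.1",
        0.0001: "D0.01",
    }
    out = [("LP", r, 0.0) for r in range(1, config.replicates + 1)]
    out += [("HP", r, 1.0) for r in range(1, config.replicates + 1)]
    for dose in config.doses:
        label = dose_labels.get(dose, f"D{dose * 100:g}")
        out += [(label, r, dose) for r in range(1, config.replicates + 1)]
    return out


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study, reproducible from ``config.seed``.

    Produces 5 pure-LP, 5 pure-HP (one optionally dropped from the count
    table, mirroring a failed sequencing run; its metadata and gas rows are
    kept), and ``replicates`` samples per invasion dose, plus the tree, gas
    series, and ground truth. Every sample consumes an independent random
    substream keyed by (treatment, replicate).
    """
    root_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lp, hp, truth = generate_sources(config, root_rng)
    tree = random_coalescent_tree(truth.asv_ids, root_rng)

    rows = []
    meta_rows = []
    gas_rows = []
    kept_sample_ids = []
    for treatment, replicate, dose in _treatment_samples(config):
        sid = f"{treatment}_R{replicate}"
        rng = sample_rng(config.seed, treatment, replicate)
        trajectory: list[float] = []
        if treatment == "LP":
            profile = transfer_dynamics(
                lp, truth, config, config.n_transfers_pre + config.n_transfers_post,
                rng, selection=False, trajectory=trajectory,
            )
        elif treatment == "HP":
            profile = transfer_dynamics(
                hp, truth, config, config.n_transfers_pre + config.n_transfers_post,
                rng, selection=False, trajectory=trajectory,
            )
        else:
            pre = transfer_dynamics(
                lp, truth, config, config.n_transfers_pre, rng,
                selection=False, trajectory=trajectory,
            )
            invaded = mix(pre, hp, dose)
            s_rep = float(
                np.expm1(
                    np.log1p(config.invader_fitness_s)
                    + rng.normal(0.0, config.fitness_rep_sigma)
                )
            )
            profile = transfer_dynamics(
                invaded, truth, config, config.n_transfers_post, rng,
                selection=True, s=s_rep, trajectory=trajectory,
            )
        truth.sample_dose[sid] = dose
        truth.invader_trajectory[sid] = trajectory

        depth = (
            config.read_depth
            if config.read_depth is not None
            else int(rng.integers(*config.read_depth_range, endpoint=True))
        )
        reads = sample_reads(profile, depth, rng)

        drop = (
            config.drop_hp_sample
            and treatment == "HP"
            and replicate == config.replicates
        )
        if not drop:
            rows.append(reads)
            kept_sample_ids.append(sid)
        meta_rows.append(
            {
                "sample_id": sid,
                "treatment": treatment,
                "replicate": replicate,
                "week": config.n_weeks,
            }
        )
        gas_rows.extend(
            gas_series(
                profile, truth, config, config.n_transfers_pre,
                treatment=treatment, sample_id=sid, rng=rng,
            )
        )

    import pandas as pd

    table = AsvCountTable(kept_sample_ids, truth.asv_ids, np.vstack(rows))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    gas = GasSeries(pd.DataFrame(gas_rows))
    return SimulatedStudy(table, metadata, tree, gas, truth, config)


# re-exported for convenience: dose labels used by the analysis modules
DOSE_OF_TREATMENT = dict(TREATMENT_DOSE)
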