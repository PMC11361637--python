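"""Synthetic regeneration datasets with known ground truth.

Emulates the structure of a zebrafish retina regeneration experiment: cells
on a Müller glia (MG) -> progenitor -> neuron differentiation trajectory,
sampled under unablated-control vs ablated and wild-type vs TF-knockout
conditions, with a planted signed TF->target regulatory network driving
negative-binomial counts, plus simulated plate-reader fluorescence screens.

Generative model
----------------
Each cell has a latent trajectory position ``t`` in [0,1], uniform in the
control condition and Beta(a, b) with a < b in the ablated condition (cells
pile up early, where MG re-activate). Each TF has a Gaussian activity bump
over ``t`` centered in its lineage module's window (MG early, progenitor
middle, neuron late). A target gene's log-rate is a baseline plus the
signed, weighted sum of its regulators' activities; rates are normalized
per cell and scaled by a log-normal library size; counts are drawn from a
negative binomial with shared dispersion. A knockout zeroes the knocked-out
TF's activity and adds a configurable positive shift to a designated
lineage module (the fate the knockout biases progenitors toward).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mgregen.preprocess import CountMatrix

__all__ = [
    "STATES",
    "SimulationConfig",
    "PlantedNetwork",
    "TrajectoryModel",
    "SyntheticDataset",
    "PlateSimConfig",
    "make_planted_network",
    "simulate_trajectory_counts",
    "simulate_conditions",
    "simulate_ablation_pair",
    "simulate_ko_pair",
    "simulate_plate_reader",
    "simulate_screen_plate",
    "true_marker_sets",
]

STATES = ("MG", "progenitor", "neuron")
# state windows on t: MG [0, 0.33), progenitor [0.33, 0.66), neuron [0.66, 1]
STATE_THRESHOLDS = (0.33, 0.66)
MODULE_CENTERS = {"MG": 0.15, "progenitor": 0.50, "neuron": 0.85}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the single-cell simulator.

    ``n_cells`` is the number of cells per condition, so the default paired
    designs (control+ablated, wild-type+knockout) carry 2000 cells total.
    """

    n_cells: int = 1000
    n_genes: int = 300
    n_tfs: int = 20
    targets_per_tf: int = 10
    negative_edge_fraction: float = 0.25
    edge_weight_range: tuple[float, float] = (0.8, 1.6)
    nb_dispersion: float = 2.0
    library_size_mean: float = 2500.0
    ablation: str = "control"  # control | ablated
    genotype: str = "wildtype"  # wildtype | knockout
    ko_tf: str | None = None
    ko_module: str = "neuron"
    ko_module_shift: float = 0.3
    ablation_time_shift: tuple[float, float] = (1.5, 3.0)
    tf_amplitude: float = 2.0
    activity_width: float = 0.13
    baseline_sd: float = 0.3
    library_size_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must be <= n_genes")
        if self.n_tfs > 0 and self.targets_per_tf > self.n_genes - self.n_tfs:
            raise ValueError(
                "targets_per_tf exceeds the number of available non-TF targets"
            )
        if not 0 <= self.negative_edge_fraction <= 1:
            raise ValueError("negative_edge_fraction must be in [0,1]")
        lo, hi = self.edge_weight_range
        if lo <= 0 or hi < lo:
            raise ValueError("edge_weight_range bounds must be positive, lo <= hi")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size_mean < 0:
            raise ValueError("library_size_mean must be >= 0")
        if self.ablation not in ("control", "ablated"):
            raise ValueError("ablation must be 'control' or 'ablated'")
        if self.genotype not in ("wildtype", "knockout"):
            raise ValueError("genotype must be 'wildtype' or 'knockout'")
        a, b = self.ablation_time_shift
        if a <= 0 or b <= 0:
            raise ValueError("ablation_time_shift Beta parameters must be positive")
        if self.ko_module not in STATES:
            raise ValueError(f"ko_module must be one of {STATES}")

    @property
    def condition(self) -> str:
        return f"{self.ablation}_{self.genotype}"


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"tf{i:03d}" for i in range(config.n_tfs)]
    targets = [f"g{i:04d}" for i in range(config.n_genes - config.n_tfs)]
    return tfs, targets


@dataclass
class PlantedNetwork:
    """Ground-truth signed, weighted TF->target edges with lineage modules."""

    edges: pd.DataFrame  # columns: tf, target, sign, weight
    lineage_modules: dict[str, list[str]]
    tf_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and (e["tf"] == e["target"]).any():
            raise ValueError("self-edges are not allowed")
        if len(e) and e.duplicated(["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) pairs")
        tf_set = set(self.tf_ids)
        for state, members in self.lineage_modules.items():
            if not set(members) <= tf_set:
                raise ValueError(f"module {state!r} contains non-TF members")

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))

    def sign_of(self) -> dict[tuple[str, str], int]:
        return {
            (t, g): int(s)
            for t, g, s in zip(self.edges["tf"], self.edges["target"],
                               self.edges["sign"])
        }


def make_planted_network(config: SimulationConfig) -> PlantedNetwork:
    """Plant a signed TF->target network with lineage-specific TF modules.

    TFs are assigned round-robin to the MG / progenitor / neuron modules;
    each TF regulates ``targets_per_tf`` distinct non-TF genes, and a
    ``negative_edge_fraction`` share of all edges (rounded) is repressive.

    The first TF of each module is the module's fate *driver* (the ascl1a /
    atoh7 role): a strong lineage-specifying activator with the module's
    largest regulon. In modules of three or more TFs the driver regulates
    twice the per-TF share (its mates split the remainder, so the module's
    and the network's edge totals are unchanged); driver edges are all
    positive with weights from the upper half of the weight range, and the
    repressive share is drawn from the remaining TFs' edges (spilling onto
    driver edges only if those alone cannot absorb it).
    """
    rng = np.random.default_rng([config.seed, 7])
    tfs, targets = _gene_ids(config)
    modules: dict[str, list[str]] = {s: [] for s in STATES}
    for i, tf in enumerate(tfs):
        modules[STATES[i % len(STATES)]].append(tf)
    drivers = {members[0] for members in modules.values() if members}
    T = config.targets_per_tf
    n_targets_of: dict[str, int] = {tf: T for tf in tfs}
    for members in modules.values():
        m = len(members)
        if m >= 3 and T >= 1:
            n_targets_of[members[0]] = 2 * T
            base, rem = divmod((m - 2) * T, m - 1)
            for j, mate in enumerate(members[1:]):
                n_targets_of[mate] = base + (1 if j < rem else 0)
    if max(n_targets_of.values(), default=0) > len(targets):
        raise ValueError(
            "targets_per_tf too large for the non-TF gene pool "
            "(the module driver needs twice the per-TF share)"
        )
    rows = []
    for tf in tfs:
        chosen = rng.choice(len(targets), size=n_targets_of[tf], replace=False)
        for j in sorted(chosen):
            rows.append((tf, targets[j]))
    n_edges = len(rows)
    is_driver_edge = np.array([tf in drivers for tf, _ in rows], dtype=bool)
    signs = np.ones(n_edges, dtype=int)
    n_neg = int(round(config.negative_edge_fraction * n_edges))
    if n_neg:
        pool = np.flatnonzero(~is_driver_edge)
        if n_neg > pool.size:
            extra = rng.choice(np.flatnonzero(is_driver_edge),
                               size=n_neg - pool.size, replace=False)
            pool = np.concatenate([pool, extra])
            chosen_neg = pool
        else:
            chosen_neg = rng.choice(pool, size=n_neg, replace=False)
        signs[chosen_neg] = -1
    lo, hi = config.edge_weight_range
    weights = rng.uniform(lo, hi, size=n_edges)
    mid = (lo + hi) / 2
    weights[is_driver_edge] = rng.uniform(mid, hi, size=int(is_driver_edge.sum()))
    edges = pd.DataFrame(
        {
            "tf": [r[0] for r in rows],
            "target": [r[1] for r in rows],
            "sign": signs,
            "weight": weights,
        }
    )
    return PlantedNetwork(edges, modules, tfs, tfs + targets)


class TrajectoryModel:
    """Deterministic expression model over the latent trajectory.

    Exposes the closed-form quantities the simulator samples around, so
    tests can compare empirical statistics against the exact model values.
    """

    def __init__(self, config: SimulationConfig, network: PlantedNetwork):
        self.config = config
        self.network = network
        rng = np.random.default_rng([config.seed, 11])
        self.gene_ids = network.gene_ids
        self.tf_ids = network.tf_ids
        n_tfs = len(self.tf_ids)
        tf_index = {t: i for i, t in enumerate(self.tf_ids)}
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        # each TF peaks inside its module's window, with per-TF centers
        # spread across the window and individual widths so that regulators
        # are correlated but distinguishable (no two TFs are duplicates)
        windows = {"MG": (0.02, 0.31), "progenitor": (0.35, 0.64),
                   "neuron": (0.68, 0.97)}
        centers = np.empty(n_tfs)
        for state, members in network.lineage_modules.items():
            lo, hi = windows[state]
            m = len(members)
            for k, tf in enumerate(members):
                centers[tf_index[tf]] = lo + (k + 0.5) / m * (hi - lo)
        centers += rng.uniform(-0.01, 0.01, size=n_tfs)
        self.centers = centers
        self.widths = config.activity_width * rng.uniform(0.7, 1.15, size=n_tfs)
        self.baselines = rng.normal(0.0, config.baseline_sd, size=len(self.gene_ids))
        # gene x TF loading: each TF drives its own transcript, plus edges
        W = np.zeros((len(self.gene_ids), n_tfs))
        for i, tf in enumerate(self.tf_ids):
            W[gene_index[tf], i] = config.tf_amplitude
        for tf, target, sign, weight in network.edges.itertuples(index=False):
            W[gene_index[target], tf_index[tf]] = sign * weight
        self.W = W
        self._tf_index = tf_index

    def activity(self, t: np.ndarray, genotype: str = "wildtype",
                 ko_tf: str | None = None) -> np.ndarray:
        """TF activity curves, shape (n_tfs, len(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        w = self.widths[:, None]
        act = np.exp(-((t[None, :] - self.centers[:, None]) ** 2) / (2 * w**2))
        if genotype == "knockout":
            shifted = self.network.lineage_modules.get(self.config.ko_module, [])
            for tf in shifted:
                act[self._tf_index[tf]] += self.config.ko_module_shift
            if ko_tf is None:
                raise ValueError("knockout genotype requires ko_tf")
            if ko_tf not in self._tf_index:
                raise ValueError(f"ko_tf {ko_tf!r} is not a TF in the network")
            act[self._tf_index[ko_tf]] = 0.0
        return act

    def log_rate(self, t: np.ndarray, genotype: str = "wildtype",
                 ko_tf: str | None = None) -> np.ndarray:
        """Unnormalized per-gene log expression rate, shape (n_genes, len(t))."""
        act = self.activity(t, genotype=genotype, ko_tf=ko_tf)
        return self.baselines[:, None] + self.W @ act

    def normalized_rate(self, t: np.ndarray, genotype: str = "wildtype",
                        ko_tf: str | None = None) -> np.ndarray:
        """Per-gene expression fractions (columns sum to 1)."""
        lam = np.exp(self.log_rate(t, genotype=genotype, ko_tf=ko_tf))
        return lam / lam.sum(axis=0, keepdims=True)

    def expected_ko_log_delta(self, t_grid: np.ndarray, ko_tf: str) -> np.ndarray:
        """Ground-truth knockout-minus-wildtype log normalized-rate difference.

        This is the oracle for the sign and location of condition deltas in
        library-normalized expression space, shape (n_genes, len(t_grid)).
        """
        p_ko = self.normalized_rate(t_grid, genotype="knockout", ko_tf=ko_tf)
        p_wt = self.normalized_rate(t_grid, genotype="wildtype")
        return np.log(p_ko) - np.log(p_wt)


@dataclass
class SyntheticDataset:
    """Counts plus the ground truth that generated them."""

    counts: CountMatrix
    true_pseudotime: np.ndarray
    state_label: np.ndarray
    condition_label: np.ndarray
    network: PlantedNetwork
    model: TrajectoryModel
    library_factor: np.ndarray

    def __post_init__(self) -> None:
        n = self.counts.n_cells
        for name in ("true_pseudotime", "state_label", "condition_label",
                     "library_factor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal number of cells")
        if not np.all(np.isfinite(self.true_pseudotime)):
            raise ValueError("true_pseudotime must be finite")


def _state_of(t: np.ndarray) -> np.ndarray:
    lo, hi = STATE_THRESHOLDS
    out = np.full(t.shape, "progenitor", dtype=object)
    out[t < lo] = "MG"
    out[t >= hi] = "neuron"
    return out.astype(str)


def _condition_key(ablation: str, genotype: str) -> int:
    return 1000 + 2 * (ablation == "ablated") + (genotype == "knockout")


def simulate_trajectory_counts(
    config: SimulationConfig,
    network: PlantedNetwork | None = None,
    model: TrajectoryModel | None = None,
) -> SyntheticDataset:
    """Sample a single-condition dataset from the trajectory model.

    Deterministic given the config (same seed -> bitwise-identical counts).
    ``network``/``model`` may be supplied to share ground truth across
    conditions; by default they are rebuilt from the config seed.
    """
    if network is None:
        network = make_planted_network(config)
    if model is None:
        model = TrajectoryModel(config, network)
    ko_tf = config.ko_tf
    if config.genotype == "knockout":
        if ko_tf is None:
            raise ValueError("knockout genotype requires ko_tf")
        if ko_tf not in network.tf_ids:
            raise ValueError(f"ko_tf {ko_tf!r} is not a TF in the network")
    rng = np.random.default_rng(
        [config.seed, _condition_key(config.ablation, config.genotype)]
    )
    if config.ablation == "ablated":
        a, b = config.ablation_time_shift
        t = rng.beta(a, b, size=config.n_cells)
    else:
        t = rng.uniform(0.0, 1.0, size=config.n_cells)
    p = model.normalized_rate(t, genotype=config.genotype, ko_tf=ko_tf)
    if config.library_size_mean == 0:
        lib = np.zeros(config.n_cells)
    else:
        sigma = config.library_size_sigma
        mu = np.log(config.library_size_mean) - sigma**2 / 2
        lib = rng.lognormal(mu, sigma, size=config.n_cells)
    mean = p * lib[None, :]
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    prefix = config.condition
    cells = [f"{prefix}_c{i:05d}" for i in range(config.n_cells)]
    cm = CountMatrix(counts.astype(np.int64), model.gene_ids, cells)
    return SyntheticDataset(
        counts=cm,
        true_pseudotime=t,
        state_label=_state_of(t),
        condition_label=np.full(config.n_cells, prefix),
        network=network,
        model=model,
        library_factor=lib,
    )


def simulate_conditions(
    config: SimulationConfig, conditions: list[tuple[str, str]]
) -> SyntheticDataset:
    """Concatenate several conditions sharing one planted network/model.

    ``config.n_cells`` is the number of cells per condition; conditions are
    (ablation, genotype) pairs drawn with condition-specific substreams of
    the config seed, so paired designs are reproducible as a family.
    """
    network = make_planted_network(config)
    model = TrajectoryModel(config, network)
    parts = [
        simulate_trajectory_counts(
            replace(config, ablation=abl, genotype=gt), network, model
        )
        for abl, gt in conditions
    ]
    counts = np.concatenate([p.counts.values for p in parts], axis=1)
    cells = [c for p in parts for c in p.counts.cell_ids]
    return SyntheticDataset(
        counts=CountMatrix(counts, model.gene_ids, cells),
        true_pseudotime=np.concatenate([p.true_pseudotime for p in parts]),
        state_label=np.concatenate([p.state_label for p in parts]),
        condition_label=np.concatenate([p.condition_label for p in parts]),
        network=network,
        model=model,
        library_factor=np.concatenate([p.library_factor for p in parts]),
    )


def simulate_ablation_pair(config: SimulationConfig) -> SyntheticDataset:
    """Control + ablated wild-type cells (the trajectory-comparison design)."""
    return simulate_conditions(
        config, [("control", "wildtype"), ("ablated", "wildtype")]
    )


def default_ko_tf(network: PlantedNetwork) -> str:
    """The designated knockout TF: the first progenitor-module TF."""
    members = network.lineage_modules.get("progenitor", [])
    if not members:
        raise ValueError("network has no progenitor-module TF to knock out")
    return members[0]


def simulate_ko_pair(config: SimulationConfig) -> tuple[SyntheticDataset, str]:
    """Ablated wild-type + ablated knockout cells sharing one network.

    Returns the combined dataset and the knocked-out TF id (``config.ko_tf``
    or, if unset, the first progenitor-module TF).
    """
    network = make_planted_network(config)
    ko_tf = config.ko_tf or default_ko_tf(network)
    cfg = replace(config, ko_tf=ko_tf)
    ds = simulate_conditions(cfg, [("ablated", "wildtype"), ("ablated", "knockout")])
    return ds, ko_tf


def true_marker_sets(network: PlantedNetwork) -> dict[str, set[str]]:
    """Ground-truth cell-type marker sets: positively regulated targets of
    each lineage module's TFs (the genes that peak in that state's window)."""
    pos = network.edges[network.edges["sign"] > 0]
    by_tf = pos.groupby("tf")["target"].agg(set)
    out: dict[str, set[str]] = {}
    for state, members in network.lineage_modules.items():
        s: set[str] = set()
        for tf in members:
            s |= by_tf.get(tf, set())
        out[state] = s
    return out


# ---------------------------------------------------------------------------
# plate-reader simulation


@dataclass(frozen=True)
class PlateSimConfig:
    """One crispant-vs-control plate-reader comparison.

    The assay noise SD is ``cv * control_mean`` in BOTH arms: the noise
    floor is a property of the fluorescence assay (measured once on
    wild-type ablated larvae), not of each arm's mean. The default cv is
    back-calculated from the screen's design (a 30% effect detectable at
    n=8/arm, alpha 0.05, power 0.80 implies a standardized effect of ~1.41).
    """

    n_wells_per_arm: int = 8
    control_mean: float = 100.0
    cv: float = 0.30 / 1.41
    effect_fraction: float = -0.30
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_wells_per_arm < 2:
            raise ValueError("n_wells_per_arm must be >= 2")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def standardized_effect(self) -> float:
        """|effect_fraction| / cv, the design's d."""
        if self.cv == 0:
            return np.inf
        return abs(self.effect_fraction) / self.cv


def simulate_plate_reader(config: PlateSimConfig) -> pd.DataFrame:
    """Simulate control and treated plate-reader arms.

    Returns a tidy frame (rep, well, arm, fluorescence): control wells at
    ``control_mean``, treated at ``control_mean * (1 + effect_fraction)``,
    Gaussian noise with sd ``cv * control_mean``, truncated at zero.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 33])
    n, reps = config.n_wells_per_arm, config.n_reps
    sd = config.cv * config.control_mean
    ctrl = rng.normal(config.control_mean, sd, size=(reps, n))
    trt = rng.normal(config.control_mean * (1 + config.effect_fraction), sd,
                     size=(reps, n))
    ctrl = np.clip(ctrl, 0.0, None)
    trt = np.clip(trt, 0.0, None)
    rows = []
    for r in range(reps):
        for i in range(n):
            rows.append((r, f"ctrl_{r:04d}_{i:02d}", "control", ctrl[r, i]))
        for i in range(n):
            rows.append((r, f"trt_{r:04d}_{i:02d}", "treated", trt[r, i]))
    return pd.DataFrame(rows, columns=["rep", "well", "arm", "fluorescence"])


def simulate_screen_plate(
    n_null: int = 73,
    n_inhibited: int = 7,
    n_enhanced: int = 11,
    effect_fraction: float = 0.5,
    n_wells_per_gene: int = 16,
    n_reference_wells: int = 16,
    n_unablated_wells: int = 8,
    unablated_mean: float = 100.0,
    regeneration_level: float = 0.32,
    cv: float = 0.30 / 1.41,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a full crispant screen plate table.

    Wild-type ablated reference wells sit at ``regeneration_level`` of the
    unablated mean (about a third of RGCs regrown by the endpoint);
    "inhibited" crispants lower that level by ``effect_fraction`` of itself,
    "enhanced" crispants raise it, nulls stay put. The assay SD is
    ``cv * ablated_mean`` for all ablated wells. Returns the well table
    (well, gene, arm, genotype, fluorescence, plate) and the true class of
    every gene.
    """
    rng = np.random.default_rng([seed, 57])
    ablated_mean = regeneration_level * unablated_mean
    sd = cv * ablated_mean
    rows = []
    truth: dict[str, str] = {}
    for i in range(n_unablated_wells):
        val = max(0.0, rng.normal(unablated_mean, cv * unablated_mean))
        rows.append((f"unabl_{i:02d}", "control", "unablated_control", "wildtype",
                     val, "plate1"))
    for i in range(n_reference_wells):
        val = max(0.0, rng.normal(ablated_mean, sd))
        rows.append((f"wtabl_{i:02d}", "wildtype_ablated", "ablated", "wildtype",
                     val, "plate1"))
    classes = (["no_effect"] * n_null + ["inhibited"] * n_inhibited
               + ["enhanced"] * n_enhanced)
    for g, cls in enumerate(classes):
        gene = f"gene{g:03d}"
        truth[gene] = cls
        shift = {"no_effect": 0.0, "inhibited": -effect_fraction,
                 "enhanced": effect_fraction}[cls]
        mean_g = ablated_mean * (1 + shift)
        for i in range(n_wells_per_gene):
            val = max(0.0, rng.normal(mean_g, sd))
            rows.append((f"{gene}_w{i:02d}", gene, "ablated", "crispant", val,
                         "plate1"))
    df = pd.DataFrame(
        rows, columns=["well", "gene", "arm", "genotype", "fluorescence", "plate"]
    )
    return df, truth
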