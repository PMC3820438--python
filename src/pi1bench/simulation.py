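"""Two-group normal expression simulations with a controlled DE fraction.

The generator emulates a two-population expression study (originally
lymphoblastoid cell lines from 60 European-ancestry and 45 Han Chinese
donors, ~47k transcripts) through a synthetic per-gene parameter table:
group means rounded to the nearest 0.1 — so equality of means is exact and
"differentially expressed" is unambiguous — and per-gene standard
deviations for each population.  Three variance regimes are supported:

* ``EV``  — both simulated groups use the group-A standard deviation;
* ``UV1`` — each group uses its own standard deviation (A, B);
* ``UV2`` — the roles are swapped (B, A).

The scenario factorial crosses sample sizes (60,45)/(16,12)/(8,6) (all at
the study's 4:3 ratio), a pi1 grid, the three variance regimes, two
rescaling factors (SD, IQR), and two input specifications (t, z): 144
initial scenarios plus 48 extended EV-only scenarios, 192 in total, each
run for 20 replicates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .stats_core import ExpressionMatrix

__all__ = [
    "GeneParameterTable",
    "ScenarioConfig",
    "SimulatedDataset",
    "synth_parameter_table",
    "simulate_dataset",
    "scenario_grid",
    "SAMPLE_SIZES",
    "PI1_INITIAL",
    "PI1_EXTENDED",
]

SAMPLE_SIZES = ((60, 45), (16, 12), (8, 6))
PI1_INITIAL = (0.01, 0.05, 0.10, 0.25)
PI1_EXTENDED = (0.005, 0.02, 0.03, 0.04)
SIM_TYPES = ("EV", "UV1", "UV2")


def _round_tenth(x: np.ndarray | float) -> np.ndarray | float:
    return np.round(np.asarray(x) * 10.0) / 10.0


@dataclass
class GeneParameterTable:
    """Per-gene simulation parameters.

    ``mu1``/``mu2`` are group means, each an exact multiple of 0.1;
    ``sd_A``/``sd_B`` are the two populations' standard deviations;
    ``is_de`` marks genes whose means differ (exactly, thanks to rounding).
    """

    mu1: np.ndarray
    mu2: np.ndarray
    sd_A: np.ndarray
    sd_B: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "sd_A", "sd_B"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.mu1) == len(self.mu2) == len(self.sd_A) == len(self.sd_B)):
            raise ValueError("parameter columns must have equal length")
        if np.any(self.sd_A <= 0) or np.any(self.sd_B <= 0):
            raise ValueError("standard deviations must be positive")

    @property
    def is_de(self) -> np.ndarray:
        return self.mu1 != self.mu2

    def __len__(self) -> int:
        return len(self.mu1)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation factorial (before replicate expansion)."""

    sim_type: str
    n1: int
    n2: int
    pi1: float
    G: int = 10_000
    rescale: str = "IQR"
    input_spec: str = "t"
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_type not in SIM_TYPES:
            raise ValueError(f"sim_type must be one of {SIM_TYPES}")
        if self.rescale not in ("SD", "IQR"):
            raise ValueError("rescale must be 'SD' or 'IQR'")
        if self.input_spec not in ("t", "z"):
            raise ValueError("input_spec must be 't' or 'z'")
        if not (0 <= self.pi1 < 1):
            raise ValueError("pi1 must lie in [0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2")

    def scenario_key(self) -> str:
        return (
            f"{self.sim_type}_n{self.n1}x{self.n2}_pi1={self.pi1}"
            f"_G{self.G}_{self.rescale}_{self.input_spec}"
        )

    def derived_seed(self, master_seed: int) -> np.random.SeedSequence:
        """Replicate-level seed: master seed x scenario hash x replicate."""
        scenario_hash = zlib.crc32(self.scenario_key().encode())
        return np.random.SeedSequence([master_seed, scenario_hash, self.replicate])


@dataclass
class SimulatedDataset:
    data: ExpressionMatrix
    truth: np.ndarray
    config: ScenarioConfig
    params: GeneParameterTable | None = field(default=None, repr=False)


def synth_parameter_table(
    G: int,
    pi1: float,
    seed,
    effect_scale: float = 0.5,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    log_sd_mean: float = -0.7,
    log_sd_sd: float = 0.6,
) -> GeneParameterTable:
    """Synthesize a gene-parameter table with exactly round(pi1 * G) DE genes.

    Baseline means are Normal(``baseline_mean``, ``baseline_sd``) rounded to
    the nearest 0.1 (log2-expression-like); the two populations' standard
    deviations are independent log-normals (log-SD mean ``log_sd_mean``, sd
    ``log_sd_sd``).  DE genes receive mu2 = round(mu1 + Delta, 0.1) with
    Delta = sign * |Normal(0, effect_scale)|, redrawn until the rounded
    means differ; non-DE genes get mu2 = mu1 exactly.
    """
    if not 0 <= pi1 < 1:
        raise ValueError("pi1 must lie in [0, 1)")
    n_de = int(round(pi1 * G))
    if n_de >= G and G > 0:
        raise ValueError("pi1 * G rounds to G; at least one null gene is required")
    rng = np.random.default_rng(seed)
    mu1 = _round_tenth(rng.normal(baseline_mean, baseline_sd, size=G))
    sd_A = np.exp(rng.normal(log_sd_mean, log_sd_sd, size=G))
    sd_B = np.exp(rng.normal(log_sd_mean, log_sd_sd, size=G))
    mu2 = mu1.copy()
    de_idx = rng.choice(G, size=n_de, replace=False) if n_de else np.array([], int)
    for i in de_idx:
        while True:
            delta = rng.choice([-1.0, 1.0]) * abs(rng.normal(0.0, effect_scale))
            cand = _round_tenth(mu1[i] + delta)
            if cand != mu1[i]:
                mu2[i] = cand
                break
    return GeneParameterTable(mu1=mu1, mu2=mu2, sd_A=sd_A, sd_B=sd_B)


def simulate_dataset(
    params: GeneParameterTable,
    config: ScenarioConfig,
    seed=None,
    master_seed: int | None = None,
) -> SimulatedDataset:
    """Draw an expression matrix from independent normals per gene and group.

    Group-1 values ~ Normal(mu1, sigma1) and group-2 ~ Normal(mu2, sigma2),
    with (sigma1, sigma2) = (sd_A, sd_A) for EV, (sd_A, sd_B) for UV1 and
    (sd_B, sd_A) for UV2.  The random stream comes from ``seed`` if given,
    else from the replicate-level derivation of ``master_seed``, else from
    ``config.seed``.
    """
    G = len(params)
    if G != config.G:
        raise ValueError(f"parameter table has {G} genes but config.G={config.G}")
    if config.sim_type == "EV":
        sd1, sd2 = params.sd_A, params.sd_A
    elif config.sim_type == "UV1":
        sd1, sd2 = params.sd_A, params.sd_B
    else:  # UV2
        sd1, sd2 = params.sd_B, params.sd_A
    if seed is None:
        seed = (
            config.derived_seed(master_seed) if master_seed is not None else config.seed
        )
    rng = np.random.default_rng(seed)
    x1 = rng.normal(params.mu1[:, None], sd1[:, None], size=(G, config.n1))
    x2 = rng.normal(params.mu2[:, None], sd2[:, None], size=(G, config.n2))
    values = np.hstack([x1, x2])
    gene_ids = np.array([f"g{i:06d}" for i in range(G)])
    group = np.array(["1"] * config.n1 + ["2"] * config.n2)
    data = ExpressionMatrix(values=values, gene_ids=gene_ids, group=group)
    return SimulatedDataset(data=data, truth=params.is_de, config=config, params=params)


def scenario_grid(stage: str = "full") -> list[ScenarioConfig]:
    """Enumerate the simulation factorial.

    ``initial``: 3 sample sizes x pi1 {0.01, 0.05, 0.10, 0.25} x
    {EV, UV1, UV2} x {SD, IQR} x {t, z} = 144 scenarios.
    ``extended``: 3 sample sizes x pi1 {0.005, 0.02, 0.03, 0.04} x EV only x
    {SD, IQR} x {t, z} = 48 scenarios.  ``full`` is their union (192).
    Replicates are expanded by the study runner, not here.
    """
    if stage not in ("initial", "extended", "full"):
        raise ValueError("stage must be 'initial', 'extended' or 'full'")
    grid: list[ScenarioConfig] = []
    if stage in ("initial", "full"):
        for (n1, n2) in SAMPLE_SIZES:
            for pi1 in PI1_INITIAL:
                for sim_type in SIM_TYPES:
                    for rescale in ("SD", "IQR"):
                        for input_spec in ("t", "z"):
                            grid.append(
                                ScenarioConfig(
                                    sim_type=sim_type, n1=n1, n2=n2, pi1=pi1,
                                    rescale=rescale, input_spec=input_spec,
                                )
                            )
    if stage in ("extended", "full"):
        for (n1, n2) in SAMPLE_SIZES:
            for pi1 in PI1_EXTENDED:
                for rescale in ("SD", "IQR"):
                    for input_spec in ("t", "z"):
                        grid.append(
                            ScenarioConfig(
                                sim_type="EV", n1=n1, n2=n2, pi1=pi1,
                                rescale=rescale, input_spec=input_spec,
                            )
                        )
    return grid
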