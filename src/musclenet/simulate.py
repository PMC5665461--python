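"""Synthetic two-breed developmental microarray data with a truth record.

The generator emulates the statistical structure the downstream analysis
assumes: normalized log2 intensities for a 2-breed x 4-stage factorial with
unbalanced biological replication, plus planted signals —

* developmentally regulated genes (stage-dependent trajectories shared by
  both breeds),
* breed-DE genes (symmetric +/-effect/2 offsets so that relabelling breeds
  negates every planted sign),
* a "mitoproteome-like" gene set whose DE signs at 260 dpc follow a
  configurable up/down skew,
* regulators, a few of which are *rewired*: their stage trajectory is
  followed by a target set in one breed only (or followed in one and
  mirrored in the other), creating differential co-expression,
* duplicate probes for a fraction of genes, and missing cells confined to a
  single treatment per probe so the 7-of-8 expression filter stays
  controllable.

Every planted signal is recorded in a :class:`SyntheticTruth` so recovery
can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import BREEDS, STAGES, TREATMENTS, make_design_frame

#: the study's array subset after quality control: 21 samples over 8 treatments
DEFAULT_REPLICATE_PLAN: dict[tuple[str, int], int] = {
    ("BA", 110): 3, ("CH", 110): 2,
    ("BA", 180): 2, ("CH", 180): 3,
    ("BA", 210): 3, ("CH", 210): 3,
    ("BA", 260): 2, ("CH", 260): 3,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    All intensities are on the log2 scale. ``replicate_plan`` maps each
    (breed, stage) treatment to its biological replicate count; the default
    is the study's unbalanced 21-sample layout. ``mito_skew_fraction`` is
    the fraction of the planted gene set whose DE sign at 260 dpc favours
    the second breed (CH-higher, i.e. negative BA-CH).
    """

    n_genes: int = 2000
    replicate_plan: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATE_PLAN))
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    replicate_noise_sd: float = 0.3
    n_devreg_genes: int = 50
    devreg_amplitude: float = 2.0
    n_de_genes: int = 40
    de_effect: float = 1.0
    de_stages: tuple[int, ...] = STAGES
    mito_set_size: int = 514
    mito_skew_fraction: float = 345 / 514
    mito_effect: float = 0.4
    n_regulators: int = 100
    rewired_regulator_count: int = 2
    rewiring_strength: float = 1.5
    latent_amplitude: float = 1.0
    duplicate_probe_fraction: float = 0.3
    missing_rate: float = 0.01
    seed: int = 1213

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_devreg_genes": self.n_devreg_genes,
            "n_de_genes": self.n_de_genes, "mito_set_size": self.mito_set_size,
            "n_regulators": self.n_regulators,
            "rewired_regulator_count": self.rewired_regulator_count,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.mito_skew_fraction <= 1.0:
            raise ValueError("mito_skew_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.rewiring_strength <= 2.0:
            raise ValueError("rewiring_strength must lie in [0, 2]")
        if self.n_devreg_genes + self.n_de_genes > self.n_genes:
            raise ValueError("n_devreg_genes + n_de_genes exceeds n_genes")
        needed = (self.n_devreg_genes + self.n_de_genes + self.mito_set_size
                  + self.n_regulators)
        if needed > self.n_genes:
            raise ValueError(
                f"planted gene classes need {needed} genes but n_genes={self.n_genes}")
        if self.rewired_regulator_count > self.n_regulators:
            raise ValueError("rewired_regulator_count exceeds n_regulators")
        if self.rewired_regulator_count > 0 and self.n_de_genes == 0:
            raise ValueError("rewired regulators need DE genes as targets")
        plan = dict(self.replicate_plan)
        unknown = set(plan) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"replicate_plan has unknown treatments: {sorted(unknown)}")
        if any(n < 0 for n in plan.values()):
            raise ValueError("replicate counts must be >= 0")
        if sum(plan.values()) == 0:
            raise ValueError("replicate_plan is empty: no samples at all")
        for breed in BREEDS:
            if sum(plan.get((breed, s), 0) for s in STAGES) == 0:
                raise ValueError(f"replicate_plan leaves breed {breed} without samples")

    def stage_index(self, stage: int) -> int:
        return STAGES.index(stage)


@dataclass
class SyntheticTruth:
    """Record of every planted signal, reproducible from (config, seed)."""

    devreg_genes: list[tuple[str, dict[int, float]]]
    de_genes: list[tuple[str, int, float]]
    mito_set: list[tuple[str, int]]                      # (gene, DE sign at 260 dpc)
    rewired_regulators: list[tuple[str, tuple[str, ...], dict[str, float]]]
    regulators: list[str]                                # rewired + background
    seed: int

    @property
    def de_gene_names(self) -> list[str]:
        return sorted({g for g, _, _ in self.de_genes})

    @property
    def devreg_gene_names(self) -> list[str]:
        return [g for g, _ in self.devreg_genes]

    @property
    def mito_gene_names(self) -> list[str]:
        return [g for g, _ in self.mito_set]


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Expand the replicate plan into a per-sample design frame.

    Sample ids are ``{breed}{stage}_{k}``; each sample is its own technical
    group (technical replicates were averaged upstream of this contract).
    """
    config.validate()
    records = []
    for breed, stage in TREATMENTS:
        for k in range(int(config.replicate_plan.get((breed, stage), 0))):
            sid = f"{breed}{stage}_{k + 1}"
            records.append({"sample_id": sid, "breed": breed, "stage": stage,
                            "tech_group": sid})
    return make_design_frame(records)


def _standardized_trajectory(rng: np.random.Generator) -> np.ndarray:
    """A random 4-stage profile with mean 0 and sample sd 1."""
    while True:
        t = rng.normal(size=len(STAGES))
        sd = t.std(ddof=1)
        if sd > 1e-8:
            return (t - t.mean()) / sd


def _orthogonal_latents(rng: np.random.Generator, k: int) -> list[np.ndarray]:
    """Random standardized stage trajectories, mutually orthogonal where possible.

    The centered 4-point space has 3 dimensions, so up to 3 latents are
    exactly orthogonal; further ones are simply random.  Orthogonality keeps
    the planted rewiring signals of distinct regulators from interfering
    with one another's correlation profiles.
    """
    n_s = len(STAGES)
    basis: list[np.ndarray] = []
    out: list[np.ndarray] = []
    for _ in range(k):
        u = None
        for _ in range(100):
            t = rng.normal(size=n_s)
            t -= t.mean()
            for b in basis:
                t -= (t @ b) * b
            norm = np.linalg.norm(t)
            if norm > 1e-6:
                u = t / norm
                break
        if u is None:  # centered space exhausted: fall back to a random one
            t = _standardized_trajectory(rng)
            out.append(t)
            continue
        if len(basis) < n_s - 1:
            basis.append(u)
        out.append(u / u.std(ddof=1))
    return out


def simulate_dataset(config: SimulationConfig):
    """Generate ``(matrix, design, probe_map, truth)``.

    The matrix holds one row per probe (>=1 probe per gene; a configurable
    fraction of genes carry a duplicate probe) and one column per sample.
    True treatment means are built as baseline + planted offsets; replicate
    values add iid N(0, replicate_noise_sd) noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(config)

    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    cursor = 0
    devreg = genes[cursor:cursor + config.n_devreg_genes]; cursor += config.n_devreg_genes
    de = genes[cursor:cursor + config.n_de_genes]; cursor += config.n_de_genes
    mito = genes[cursor:cursor + config.mito_set_size]; cursor += config.mito_set_size
    regulators = genes[cursor:cursor + config.n_regulators]; cursor += config.n_regulators
    rewired = regulators[:config.rewired_regulator_count]

    n_b, n_s = len(BREEDS), len(STAGES)
    # true mean per (gene, breed, stage)
    mu = np.tile(rng.normal(config.baseline_mean, config.baseline_sd,
                            size=config.n_genes)[:, None, None], (1, n_b, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}

    devreg_truth: list[tuple[str, dict[int, float]]] = []
    for g in devreg:
        traj = config.devreg_amplitude * _standardized_trajectory(rng)
        mu[gene_pos[g], :, :] += traj[None, :]
        devreg_truth.append((g, dict(zip(STAGES, traj))))

    # breed effects are split symmetrically (+e/2 BA, -e/2 CH) so that
    # relabelling breeds exactly negates every planted DE sign
    de_truth: list[tuple[str, int, float]] = []
    de_signs = np.where(rng.random(config.n_de_genes) < 0.5, -1.0, 1.0)
    for g, sign in zip(de, de_signs):
        for s in config.de_stages:
            eff = sign * config.de_effect
            si = config.stage_index(s)
            mu[gene_pos[g], 0, si] += eff / 2.0
            mu[gene_pos[g], 1, si] -= eff / 2.0
            de_truth.append((g, s, eff))

    mito_truth: list[tuple[str, int]] = []
    if config.mito_set_size:
        n_down = int(round(config.mito_skew_fraction * config.mito_set_size))
        signs = np.array([-1] * n_down + [1] * (config.mito_set_size - n_down))
        rng.shuffle(signs)
        si = config.stage_index(260)
        for g, sign in zip(mito, signs):
            eff = sign * config.mito_effect
            mu[gene_pos[g], 0, si] += eff / 2.0
            mu[gene_pos[g], 1, si] -= eff / 2.0
            mito_truth.append((g, int(sign)))

    # rewiring: the regulator follows a latent stage trajectory in both
    # breeds; its targets (same-signed planted DE genes, partitioned among
    # rewired regulators) follow it in BA only for strength <= 1, and
    # additionally mirror it in CH for strength > 1
    rewired_truth: list[tuple[str, tuple[str, ...], dict[str, float]]] = []
    if rewired:
        w_ba = min(config.rewiring_strength, 1.0)
        w_ch = -max(config.rewiring_strength - 1.0, 0.0)
        pos_de = [g for g, sign in zip(de, de_signs) if sign > 0]
        neg_de = [g for g, sign in zip(de, de_signs) if sign < 0]
        pools = [pos_de, neg_de]
        latents = _orthogonal_latents(rng, len(rewired))
        for r_i, reg in enumerate(rewired):
            latent = latents[r_i]
            mu[gene_pos[reg], :, :] += config.latent_amplitude * latent[None, :]
            pool = pools[r_i % 2]
            targets = tuple(pool[r_i // 2::max(1, (len(rewired) + 1) // 2)])
            if not targets:  # more rewired regulators than sign-pools allow
                targets = tuple(de[r_i::len(rewired)])
            for t in targets:
                mu[gene_pos[t], 0, :] += config.latent_amplitude * w_ba * latent
                mu[gene_pos[t], 1, :] += config.latent_amplitude * w_ch * latent
            rewired_truth.append((reg, targets, {"BA": w_ba, "CH": w_ch}))

    # probes: one per gene plus a duplicate (with a small abundance shift)
    # for a fraction of genes, emulating many-to-one probe->gene mapping
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    probe_shift: list[float] = []
    dup_mask = rng.random(config.n_genes) < config.duplicate_probe_fraction
    for i, g in enumerate(genes):
        probe_ids.append(f"P_{g}_1")
        probe_gene.append(g)
        probe_shift.append(0.0)
        if dup_mask[i]:
            probe_ids.append(f"P_{g}_2")
            probe_gene.append(g)
            probe_shift.append(float(rng.normal(0.0, 0.5)))

    sample_breed = design["breed"].map({b: i for i, b in enumerate(BREEDS)}).to_numpy()
    sample_stage = design["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    gene_idx = np.array([gene_pos[g] for g in probe_gene])
    base = mu[gene_idx][:, sample_breed, sample_stage]  # probes x samples
    base = base + np.asarray(probe_shift)[:, None]
    values = base + rng.normal(0.0, config.replicate_noise_sd, size=base.shape)

    if config.missing_rate > 0.0:
        # confine all missing cells of a probe to one designated treatment,
        # preserving the overall per-cell rate in expectation
        treat_of_sample = sample_breed * n_s + sample_stage
        n_samples = len(design)
        designated = rng.integers(0, len(TREATMENTS), size=len(probe_ids))
        in_designated = treat_of_sample[None, :] == designated[:, None]
        cells_per_treat = np.bincount(treat_of_sample, minlength=len(TREATMENTS))
        p_cell = np.minimum(
            1.0, config.missing_rate * n_samples / np.maximum(cells_per_treat[designated], 1))
        blank = in_designated & (rng.random(values.shape) < p_cell[:, None])
        values = np.where(blank, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=design.index)
    probe_map = pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"),
                          name="gene")
    truth = SyntheticTruth(devreg_genes=devreg_truth, de_genes=de_truth,
                           mito_set=mito_truth, rewired_regulators=rewired_truth,
                           regulators=list(regulators), seed=config.seed)
    return matrix, design, probe_map, truth
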