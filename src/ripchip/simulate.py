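"""Synthetic two-color RIP-Chip experiments with known ground truth.

The generator emulates the structure of a spotted-array RNA
co-immunoprecipitation (RIP-Chip) study: five biological replicates each of a
specific IP, a mock (isotype control IgG) IP, and total RNA, hybridized
against a common universal-reference RNA on ~3.6e4-probe two-color arrays.

Model
-----
Each expressed probe carries a latent log2 abundance drawn from a normal
distribution; its linear-scale signal rides on an additive gamma-distributed
local background, giving raw foreground/background intensities on which the
">2-fold over background" expression filter has real work to do. A small
planted fraction of expressed probes is truly enriched in the IP channel by
``planted_log2_fold`` log2 units over mock; everything else is null.
Replicate noise is multiplicative log-normal. A smooth sinusoidal
intensity-dependent dye bias (in M as a function of A, random phase per
array) is injected into the sample channel so within-array loess
normalization is exercised. The reference channel's expectation equals the
probe's baseline abundance on every array, emulating a pooled reference that
resembles the samples.

Gene sets are simulated alongside: one designated "histone-like" set draws
most of its members from the planted targets (a positive control for
enrichment testing); the remaining sets are uniform draws from expressed
probes (null sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrayio import ArrayScan, GeneSetCollection, write_gmt, write_manifest, write_scan

HISTONE_LIKE_SET = "HISTONE_LIKE"


@dataclass
class SimulationParams:
    """Parameters of a synthetic RIP-Chip experiment.

    Defaults reproduce the study design: ~3.6e4 probes, 5 biological
    replicates per condition, ~1.5% truly IP-enriched probes with a mean
    log2 enrichment of 3 over mock.
    """

    n_probes: int = 36000
    n_replicates: int = 5
    target_fraction: float = 0.015
    planted_log2_fold: float = 3.0
    replicate_noise_sd: float = 0.35
    background_mean: float = 200.0
    expressed_fraction: float = 0.4
    dye_bias_amplitude: float = 0.5
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 100)
    set_target_overlap: float = 0.9
    probe_copies: int = 1          # within-slide replicate spots per probe id
    abundance_mean_log2: float = 11.0
    abundance_sd_log2: float = 1.5
    offscale_mean_log2: float = 4.0   # residual signal of non-expressed probes
    offscale_sd_log2: float = 1.0
    background_shape: float = 4.0  # gamma shape of local background
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must be in (0, 1)")
        if not 0.0 < self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must be in (0, 1]")
        if self.target_fraction >= self.expressed_fraction:
            raise ValueError("target_fraction must be smaller than expressed_fraction")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if self.dye_bias_amplitude < 0:
            raise ValueError("dye_bias_amplitude must be >= 0")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")
        if self.n_gene_sets < 1:
            raise ValueError("n_gene_sets must be >= 1")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("set_size_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.set_target_overlap <= 1.0:
            raise ValueError("set_target_overlap must be in [0, 1]")
        if self.probe_copies < 1:
            raise ValueError("probe_copies must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by unique probe id."""

    probe_ids: np.ndarray
    planted_target_flags: np.ndarray
    true_log2_fold: np.ndarray
    expressed_flags: np.ndarray
    gene_set_membership: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted_ids(self) -> np.ndarray:
        return self.probe_ids[self.planted_target_flags]

    @property
    def n_planted(self) -> int:
        return int(self.planted_target_flags.sum())


def generate_experiment(params: SimulationParams
                        ) -> tuple[list[ArrayScan], GroundTruth]:
    """Simulate scans for all three conditions plus the planted ground truth.

    Returns ``3 * n_replicates`` :class:`~ripchip.arrayio.ArrayScan` objects
    (roles IP, mock, total) and a :class:`GroundTruth`. Fully deterministic
    under ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_probes

    probe_ids = np.array([f"PR{i:06d}" for i in range(n)], dtype=object)

    n_expressed = int(round(params.expressed_fraction * n))
    n_planted = int(round(params.target_fraction * n))
    expressed_idx = rng.choice(n, size=n_expressed, replace=False)
    expressed = np.zeros(n, dtype=bool)
    expressed[expressed_idx] = True
    planted_idx = rng.choice(expressed_idx, size=n_planted, replace=False)
    planted = np.zeros(n, dtype=bool)
    planted[planted_idx] = True

    true_fold = np.zeros(n)
    true_fold[planted] = params.planted_log2_fold

    # latent baseline log2 abundance; non-expressed probes emit only a faint
    # residual signal well below the background level
    abundance = np.empty(n)
    abundance[expressed] = rng.normal(params.abundance_mean_log2,
                                      params.abundance_sd_log2, size=n_expressed)
    abundance[~expressed] = rng.normal(params.offscale_mean_log2,
                                       params.offscale_sd_log2,
                                       size=n - n_expressed)
    ref_signal_log2 = abundance.copy()  # pooled reference mirrors baseline

    gene_sets = _simulate_gene_sets(params, rng, probe_ids, expressed, planted)
    truth = GroundTruth(probe_ids=probe_ids, planted_target_flags=planted,
                        true_log2_fold=true_fold, expressed_flags=expressed,
                        gene_set_membership=gene_sets)

    spot_ids = np.repeat(probe_ids, params.probe_copies)
    spot_of = np.repeat(np.arange(n), params.probe_copies)
    n_spots = len(spot_ids)
    bg_scale = params.background_mean / params.background_shape

    scans: list[ArrayScan] = []
    for role in ("IP", "mock", "total"):
        effect = true_fold if role == "IP" else np.zeros(n)
        for rep in range(1, params.n_replicates + 1):
            sample_log2 = abundance + effect
            if params.replicate_noise_sd > 0:
                sample_log2 = sample_log2 + rng.normal(
                    0.0, params.replicate_noise_sd, size=n)
                ref_log2 = ref_signal_log2 + rng.normal(
                    0.0, params.replicate_noise_sd, size=n)
            else:
                ref_log2 = ref_signal_log2.copy()

            if params.dye_bias_amplitude > 0:
                # smooth intensity-dependent bias: half a sine cycle across
                # the A range (random phase per array), gentle enough that a
                # loess fit at the pipeline's default span can remove it
                a = 0.5 * (sample_log2 + ref_log2)
                lo, hi = a.min(), a.max()
                span = max(hi - lo, 1e-12)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                bias = params.dye_bias_amplitude * np.sin(
                    np.pi * (a - lo) / span + phase)
                sample_log2 = sample_log2 + bias

            sample_sig = np.exp2(sample_log2)[spot_of]
            ref_sig = np.exp2(ref_log2)[spot_of]
            sample_bg = rng.gamma(params.background_shape, bg_scale, size=n_spots)
            ref_bg = rng.gamma(params.background_shape, bg_scale, size=n_spots)
            scans.append(ArrayScan(
                probe_ids=spot_ids,
                sample_fg=sample_sig + sample_bg,
                sample_bg=sample_bg,
                ref_fg=ref_sig + ref_bg,
                ref_bg=ref_bg,
                role=role,
                replicate=rep,
            ))
    return scans, truth


def _simulate_gene_sets(params: SimulationParams, rng: np.random.Generator,
                        probe_ids: np.ndarray, expressed: np.ndarray,
                        planted: np.ndarray) -> dict[str, list[str]]:
    """One planted-overlapping "histone-like" set plus uniform null sets."""
    lo, hi = params.set_size_range
    expressed_ids = probe_ids[expressed]
    planted_ids = probe_ids[planted]
    nonplanted_ids = probe_ids[expressed & ~planted]
    sets: dict[str, list[str]] = {}

    size = int(rng.integers(lo, hi + 1))
    size = min(size, len(expressed_ids))
    n_from_planted = min(int(round(params.set_target_overlap * size)),
                         len(planted_ids))
    members = list(rng.choice(planted_ids, size=n_from_planted, replace=False))
    n_fill = min(size - n_from_planted, len(nonplanted_ids))
    if n_fill > 0:
        members += list(rng.choice(nonplanted_ids, size=n_fill, replace=False))
    sets[HISTONE_LIKE_SET] = members

    for k in range(1, params.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(expressed_ids))
        sets[f"NULL_SET_{k:03d}"] = list(
            rng.choice(expressed_ids, size=size, replace=False))
    return sets


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as TSV (probe_id, planted, true_log2_fold, expressed)."""
    df = pd.DataFrame({
        "probe_id": truth.probe_ids,
        "planted": truth.planted_target_flags.astype(int),
        "true_log2_fold": truth.true_log2_fold,
        "expressed": truth.expressed_flags.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return GroundTruth(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        planted_target_flags=df["planted"].to_numpy(dtype=bool),
        true_log2_fold=df["true_log2_fold"].to_numpy(dtype=float),
        expressed_flags=df["expressed"].to_numpy(dtype=bool),
    )


def write_experiment(scans: list[ArrayScan], truth: GroundTruth,
                     out_dir: str | Path) -> Path:
    """Write scans as GPR-style files plus a manifest, truth TSV and GMT.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for scan in scans:
        fname = f"{scan.role}_rep{scan.replicate}.gpr"
        write_scan(scan, out / fname)
        entries.append((fname, scan.role, scan.replicate))
    manifest = out / "samples.tsv"
    write_manifest(entries, manifest)
    write_truth(truth, out / "truth.tsv")
    if truth.gene_set_membership:
        coll = GeneSetCollection(sets={
            name: ("simulated", list(members))
            for name, members in truth.gene_set_membership.items()})
        write_gmt(coll, out / "gene_sets.gmt")
    return manifest
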