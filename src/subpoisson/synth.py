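"""Ground-truthed synthetic smFISH populations and spot tables.

Emulates the statistical structure the estimators assume: per-cell mRNA counts
drawn from the kinetic model at steady state (via exact SSA), mean expression
scaling with cell size (transcription-cycle rates proportional to length, so
concentration homeostasis emerges), unimodal single-molecule spot intensities
(log-normal, median 1, configurable CV), multi-mRNA transcription-site spots
whose intensity is the sum of the per-molecule intensities, per-image gain
differences, nuclear/cytoplasmic partitioning, and an optional rate of
transcription sites falling just outside the nuclear mask.

It does not render images or optics, simulate the cell cycle, or reproduce any
specific gene's empirical distribution; binucleated cells are emulated
phenomenologically by a synthesis-rate multiplier plus the stratum flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelSpec, build_network, steady_state_moments
from .ssa import _final_states

__all__ = ["SynthConfig", "GroundTruth", "RoundtripReport",
           "generate_population", "render_spot_table", "roundtrip_check"]


@dataclass(frozen=True)
class SynthConfig:
    """Ground truth and acquisition model for one synthetic experiment.

    Lengths are uniform on ``length_range`` (default 7-14 um, the fission
    yeast interphase growth range); widths are near-constant.  With
    ``size_scaling`` the synthesis-cycle rates (k_A and k_B jointly) scale
    linearly with length relative to the population median.  ``intensity_cv``
    is the coefficient of variation of single-molecule spot intensities
    (measured range 0.24-0.37; default 0.3).
    """

    spec: ModelSpec
    seed: int
    n_cells: int = 2000
    length_range: tuple[float, float] = (7.0, 14.0)
    width_mean: float = 3.6
    width_sd: float = 0.2
    size_scaling: bool = True
    intensity_cv: float = 0.3
    nascent_mean: float = 1.0
    nascent_distance_scale: float = 0.15   # um, FISH spot to TS marker
    mature_distance_scale: float = 1.5     # um, nucleoplasmic spots
    binucleate_fraction: float = 0.0
    binucleate_multiplier: float = 2.0
    nuclear_mask_error_rate: float = 0.0
    nucleus_expanded: bool = True          # provenance flag: expanded-nucleus mode
    n_images: int = 4
    n_replicates: int = 1
    burn_in_lifetimes: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity_cv <= 1.0):
            raise ValueError("intensity_cv must be in [0, 1]")
        for name in ("binucleate_fraction", "nuclear_mask_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "spec"}
        d["length_range"] = list(self.length_range)
        d["spec"] = self.spec.to_dict()
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell true counts; consistent with the emitted spot table by construction.

    ``nuclear_count`` is mature nuclear mRNA (the model's MN species);
    ``nascent_count`` are transcripts at the TS (drawn separately, since the
    kinetic model excludes nascent dynamics); ``cytoplasmic_count`` is total
    cytoplasmic mRNA.
    """

    cells: pd.DataFrame
    config: SynthConfig

    @property
    def nuclear_total(self) -> np.ndarray:
        """All physically nuclear mRNAs: mature nucleoplasmic plus nascent."""
        return (self.cells["nuclear_count"] + self.cells["nascent_count"]).to_numpy()


def generate_population(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cell population and its true per-cell counts.

    Returns the cell-record table the quantification module consumes
    (image/cell ids, length, width, nucleus count, replicate) and the
    :class:`GroundTruth` carrying the hidden counts.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_cells
    lengths = rng.uniform(*config.length_range, size=n)
    widths = np.clip(rng.normal(config.width_mean, config.width_sd, size=n), 2.5, 4.5)
    binuc = rng.random(n) < config.binucleate_fraction
    n_nuclei = np.where(binuc, 2, 1)

    scale = lengths / np.median(lengths) if config.size_scaling else np.ones(n)
    synth_scale = scale * np.where(binuc, config.binucleate_multiplier, 1.0)

    network = build_network(config.spec)
    rate_matrix = np.tile(network.rate_constants, (n, 1))
    scaled = [j for j, lbl in enumerate(network.reaction_labels)
              if lbl.startswith("remodel") or lbl == "synthesis"]
    rate_matrix[:, scaled] *= synth_scale[:, None]

    t_end = config.burn_in_lifetimes * config.spec.effective_lifetime
    states = _final_states(network, rate_matrix, t_end,
                           seed=int(rng.integers(2**31 - 1)))
    nuclear = states[:, network.nuclear_index]
    cyto = states[:, list(network.cytoplasmic_indices)].sum(axis=1)
    nascent = rng.poisson(config.nascent_mean * synth_scale * n_nuclei)

    images_per_rep = max(1, config.n_images // config.n_replicates)
    rep_idx = np.arange(n) % config.n_replicates
    img_idx = (np.arange(n) // config.n_replicates) % images_per_rep
    replicate_id = np.array([f"rep{r + 1}" for r in rep_idx])
    image_id = np.array([f"rep{r + 1}_img{i + 1}" for r, i in zip(rep_idx, img_idx)])

    truth_cells = pd.DataFrame({
        "image_id": image_id,
        "cell_id": np.arange(n),
        "replicate_id": replicate_id,
        "length": lengths,
        "width": widths,
        "n_nuclei": n_nuclei,
        "nuclear_count": nuclear,
        "cytoplasmic_count": cyto,
        "nascent_count": nascent,
        "synth_scale": synth_scale,
    })
    cell_table = truth_cells[
        ["image_id", "cell_id", "length", "width", "n_nuclei", "replicate_id"]
    ].copy()
    cell_table["n_gfp_spots"] = 1
    cell_table["cytoplasmic_gfp"] = False
    return cell_table, GroundTruth(cells=truth_cells, config=config)


def _lognormal_unit_median(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal with median exactly 1 and the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def render_spot_table(truth: GroundTruth, config: SynthConfig | None = None) -> pd.DataFrame:
    """Emit the spot table implied by the ground truth.

    One spot per mature mRNA; all nascent mRNAs of a cell merge into a single
    TS spot whose intensity is the sum of per-molecule intensities.  Raw
    amplitudes carry a per-image gain so that per-image normalization is
    exercised.  The TS spot's compartment label is corrupted to 'cytoplasmic'
    at the nuclear-mask error rate; no other labels are corrupted.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    cells = truth.cells
    gains = {img: g for img, g in zip(
        np.unique(cells["image_id"]),
        rng.uniform(0.6, 1.8, size=cells["image_id"].nunique()),
    )}
    centers = np.column_stack([
        cells["cell_id"].to_numpy() * 30.0,
        np.zeros(len(cells)),
        np.zeros(len(cells)),
    ])

    frames = []
    for kind, count_col, dist_scale, sigma in (
        ("cytoplasmic", "cytoplasmic_count", 2.0 * config.mature_distance_scale, 0.30),
        ("mature_nuclear", "nuclear_count", config.mature_distance_scale, 0.25),
    ):
        counts = cells[count_col].to_numpy()
        total = int(counts.sum())
        if total == 0:
            continue
        cell_rows = np.repeat(np.arange(len(cells)), counts)
        dist = dist_scale * np.exp(rng.normal(0.0, sigma, size=total))
        pos = centers[cell_rows] + _random_directions(rng, total) * dist[:, None]
        frames.append(pd.DataFrame({
            "image_id": cells["image_id"].to_numpy()[cell_rows],
            "cell_id": cells["cell_id"].to_numpy()[cell_rows],
            "replicate_id": cells["replicate_id"].to_numpy()[cell_rows],
            "compartment": "cytoplasmic" if kind == "cytoplasmic" else "nuclear",
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "molecule_intensity": _lognormal_unit_median(rng, config.intensity_cv, total),
            "nearest_ts_distance": dist,
            "true_molecules": 1,
        }))

    # merged TS spots
    nasc = cells["nascent_count"].to_numpy()
    has_ts = nasc > 0
    if has_ts.any():
        rows = np.nonzero(has_ts)[0]
        per_mol = [
            _lognormal_unit_median(rng, config.intensity_cv, int(nasc[i])).sum()
            for i in rows
        ]
        dist = config.nascent_distance_scale * np.exp(rng.normal(0.0, 0.25, size=rows.size))
        pos = centers[rows] + _random_directions(rng, rows.size) * dist[:, None]
        mislabeled = rng.random(rows.size) < config.nuclear_mask_error_rate
        frames.append(pd.DataFrame({
            "image_id": cells["image_id"].to_numpy()[rows],
            "cell_id": cells["cell_id"].to_numpy()[rows],
            "replicate_id": cells["replicate_id"].to_numpy()[rows],
            "compartment": np.where(mislabeled, "cytoplasmic", "nuclear"),
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "molecule_intensity": per_mol,
            "nearest_ts_distance": dist,
            "true_molecules": nasc[rows],
        }))

    spots = pd.concat(frames, ignore_index=True)
    spots["intensity"] = (
        spots["molecule_intensity"] * spots["image_id"].map(gains).to_numpy()
    )
    return spots.drop(columns="molecule_intensity")


@dataclass(frozen=True)
class RoundtripReport:
    """End-to-end calibration of the counting and noise estimators."""

    count_bias: dict                 # method -> {'cytoplasmic': .., 'nuclear': ..}
    fano_corrected: float
    fano_corrected_se: float
    fano_analytic: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "count_bias": self.count_bias,
            "fano_corrected": self.fano_corrected,
            "fano_corrected_se": self.fano_corrected_se,
            "fano_analytic": self.fano_analytic,
            "n_cells": self.n_cells,
        }


def roundtrip_check(config: SynthConfig, n_boot: int = 2000) -> RoundtripReport:
    """generate -> render -> count -> summarize, compared against ground truth.

    Reports the relative bias of each counting method (total estimated over
    total true molecules, minus one, per compartment) and the size-corrected
    Fano factor of hybrid cytoplasmic counts in mononucleated cells against
    the analytic steady-state value.
    """
    from .quant import count_cells, normalize_intensities, size_corrected_fano

    cell_table, truth = generate_population(config)
    spots = normalize_intensities(render_spot_table(truth, config))

    true_cyto = truth.cells["cytoplasmic_count"].sum()
    true_nuc = truth.nuclear_total.sum()
    bias = {}
    hybrid_wide = None
    for method in ("spot", "intensity", "hybrid"):
        counts = count_cells(spots, method=method, cells=cell_table)
        by_comp = counts.groupby("compartment")["count"].sum()
        bias[method] = {
            "cytoplasmic": float(by_comp.get("cytoplasmic", 0) / true_cyto - 1.0),
            "nuclear": float(by_comp.get("nuclear", 0) / true_nuc - 1.0),
        }
        if method == "hybrid":
            hybrid_wide = counts

    mono = truth.cells["n_nuclei"] == 1
    merged = (
        hybrid_wide[hybrid_wide["compartment"] == "cytoplasmic"]
        .merge(truth.cells.loc[mono, ["image_id", "cell_id", "length"]],
               on=["image_id", "cell_id"])
    )
    fano = size_corrected_fano(
        merged["count"].to_numpy(), merged["length"].to_numpy(),
        n_boot=n_boot, seed=config.seed,
    )
    analytic = steady_state_moments(config.spec).fano_cytoplasmic
    return RoundtripReport(
        count_bias=bias, fano_corrected=fano.value, fano_corrected_se=fano.se,
        fano_analytic=float(analytic), n_cells=len(merged),
    )
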