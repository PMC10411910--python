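"""Likelihood-free inference of the kinetic rates by ABC rejection sampling.

Rates ``(k_A, k_B, k_C)`` are inferred relative to the effective cytoplasmic
degradation rate (``k_D`` fixed at ``R``), for a fixed number of transcription
and degradation steps ``(S, R)``.  Observed data are reduced to four summary
statistics -- nuclear and cytoplasmic mean and Fano factor -- and proposals
are scored by the Euclidean distance between model and data summaries after
standardizing each component by its observed value.  Model summaries come from
the exact analytic moments, so no per-proposal stochastic simulation is
needed; an SSA backend is retained for validation.  Model selection over
candidate ``(S, R)`` pairs uses acceptance rates at a common absolute
tolerance under a uniform model prior.

The nuclear-to-total mRNA fraction is deliberately excluded from the summary
set so it remains available as an independent check on fitted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, steady_state_moments
from .quant import size_corrected_fano
from .ssa import sample_population

__all__ = [
    "SummaryVector",
    "ABCPosterior",
    "ModelChoiceResult",
    "DEFAULT_PRIORS",
    "summarize",
    "abc_rejection",
    "model_selection",
    "posterior_summary",
]

PARAM_NAMES = ("kA", "kB", "kC")

#: log-uniform prior bounds, in effective-lifetime units
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "kA": (1e-1, 1e3), "kB": (1e-1, 1e3), "kC": (1e-1, 1e3),
}


@dataclass(frozen=True)
class SummaryVector:
    mean_nuclear: float
    mean_cytoplasmic: float
    fano_nuclear: float
    fano_cytoplasmic: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"summary entries must be finite, got {arr}")
        if self.mean_nuclear <= 0 or self.mean_cytoplasmic <= 0:
            raise ValueError("summary means must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_nuclear, self.mean_cytoplasmic,
             self.fano_nuclear, self.fano_cytoplasmic]
        )


def summarize(
    nuclear_counts,
    cytoplasmic_counts,
    sizes=None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SummaryVector:
    """Summary statistics of a per-cell dataset (mononucleated stratum).

    Fano factors are size-corrected when ``sizes`` is given (as for real
    data), raw otherwise (as for model samples, which carry no size
    covariate).
    """
    nuc = np.asarray(nuclear_counts, dtype=float)
    cyt = np.asarray(cytoplasmic_counts, dtype=float)
    if nuc.size == 0 or cyt.size == 0:
        raise ValueError("empty dataset")
    if nuc.size < 30:
        warnings.warn("fewer than 30 cells; summaries are low-precision",
                      UserWarning, stacklevel=2)
    if sizes is not None:
        fano_n = size_corrected_fano(nuc, sizes, n_boot=n_boot, seed=seed).value
        fano_c = size_corrected_fano(cyt, sizes, n_boot=n_boot, seed=seed).value
    else:
        fano_n = nuc.var(ddof=1) / nuc.mean()
        fano_c = cyt.var(ddof=1) / cyt.mean()
    return SummaryVector(
        mean_nuclear=float(nuc.mean()), mean_cytoplasmic=float(cyt.mean()),
        fano_nuclear=float(fano_n), fano_cytoplasmic=float(fano_c),
    )


def model_summary(spec: ModelSpec) -> SummaryVector:
    """Exact model summaries from the analytic steady-state moments."""
    sol = steady_state_moments(spec)
    return SummaryVector(
        mean_nuclear=sol.mean_nuclear, mean_cytoplasmic=sol.mean_cytoplasmic,
        fano_nuclear=sol.fano_nuclear, fano_cytoplasmic=sol.fano_cytoplasmic,
    )


@dataclass(frozen=True)
class ABCPosterior:
    """Accepted draws of (kA, kB, kC) with their distances."""

    draws: np.ndarray          # (n_accepted, 3)
    distances: np.ndarray
    tolerance: float
    n_proposals: int
    priors: dict
    seed: int
    S: int
    R: int

    def __post_init__(self) -> None:
        if np.any(self.distances > self.tolerance + 1e-12):
            raise ValueError("accepted distances exceed the tolerance")
        for i, name in enumerate(PARAM_NAMES):
            lo, hi = self.priors[name]
            if np.any(self.draws[:, i] < lo * (1 - 1e-9)) or np.any(
                self.draws[:, i] > hi * (1 + 1e-9)
            ):
                raise ValueError(f"accepted {name} draws outside prior support")

    @property
    def n_accepted(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(PARAM_NAMES))
        df["distance"] = self.distances
        return df

    def write(self, path) -> None:
        from .io import write_table_with_sidecar

        write_table_with_sidecar(
            self.to_frame(), path,
            metadata={
                "S": self.S, "R": self.R, "priors": {k: list(v) for k, v in self.priors.items()},
                "n_proposals": self.n_proposals, "tolerance": float(self.tolerance),
                "seed": self.seed,
            },
        )


def standardized_distance(model: SummaryVector, data: SummaryVector) -> float:
    """Euclidean distance after dividing each component by its observed value.

    Standardizing by the data summary makes the distance invariant to
    rescaling any summary component by a constant (applied to both vectors),
    so summaries on different scales contribute comparably.
    """
    s = model.as_array()
    t = data.as_array()
    return float(np.sqrt((((s - t) / t) ** 2).sum()))


def _draw_priors(rng: np.random.Generator, priors: dict, n: int) -> np.ndarray:
    cols = []
    for name in PARAM_NAMES:
        lo, hi = priors[name]
        cols.append(10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n))
    return np.column_stack(cols)


def _distances(
    proposals: np.ndarray,
    data: SummaryVector,
    S: int,
    R: int,
    backend: str,
    n_cells_per_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    target = data.as_array()
    d = np.empty(proposals.shape[0])
    for i, (ka, kb, kc) in enumerate(proposals):
        spec = ModelSpec.effective(S, R, k_A=ka, k_B=kb, k_C=kc)
        if backend == "analytic":
            s = model_summary(spec).as_array()
        else:
            pop = sample_population(
                spec, n_cells_per_sim, seed=int(rng.integers(2**31 - 1))
            )
            s = summarize(pop.nuclear, pop.cytoplasmic).as_array()
        d[i] = np.sqrt((((s - target) / target) ** 2).sum())
    return d


def abc_rejection(
    data_summary: SummaryVector,
    S: int,
    R: int,
    priors: dict | None = None,
    n_proposals: int = 10_000,
    tolerance_quantile: float = 0.01,
    seed: int = 0,
    backend: str = "analytic",
    n_cells_per_sim: int = 2000,
) -> ABCPosterior:
    """ABC rejection sampler for (kA, kB, kC) at fixed (S, R).

    Draws proposals from independent log-uniform priors, computes the model
    summaries (analytically by default), and accepts the ``tolerance_quantile``
    fraction with the smallest standardized Euclidean distance to the data
    summaries.  Reproducible for a fixed seed.
    """
    if backend not in ("analytic", "ssa"):
        raise ValueError("backend must be 'analytic' or 'ssa'")
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    n_accept = int(round(tolerance_quantile * n_proposals))
    if n_accept < 1:
        raise ValueError(
            "tolerance_quantile * n_proposals < 1 would accept nothing; "
            "increase the tolerance or the number of proposals"
        )
    rng = np.random.default_rng(seed)
    proposals = _draw_priors(rng, priors, n_proposals)
    d = _distances(proposals, data_summary, S, R, backend, n_cells_per_sim, rng)
    order = np.argsort(d, kind="stable")[:n_accept]
    return ABCPosterior(
        draws=proposals[order], distances=d[order], tolerance=float(d[order].max()),
        n_proposals=n_proposals, priors=priors, seed=seed, S=S, R=R,
    )


@dataclass(frozen=True)
class ModelChoiceResult:
    """Approximate posterior model probabilities from acceptance rates."""

    table: pd.DataFrame        # columns: S, R, accepted, probability
    tolerance: float
    n_proposals: int
    seed: int
    ties: tuple = ()

    def write(self, path) -> None:
        from .io import write_table_with_sidecar

        write_table_with_sidecar(
            self.table, path,
            metadata={"tolerance": float(self.tolerance),
                      "n_proposals": self.n_proposals, "seed": self.seed},
        )


def model_selection(
    data_summary: SummaryVector,
    candidates: list[tuple[int, int]],
    priors: dict | None = None,
    n_proposals: int = 10_000,
    tolerance: float = 0.3,
    seed: int = 0,
) -> ModelChoiceResult:
    """Bayesian model choice over candidate (S, R) pairs by ABC acceptance.

    Under a uniform model prior, the posterior probability of each candidate
    is approximated by its share of proposals accepted at a *common absolute*
    tolerance.  Exact ties for the top model are reported, never silently
    broken.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    rng = np.random.default_rng(seed)
    rows = []
    for S, R in candidates:
        proposals = _draw_priors(rng, priors, n_proposals)
        d = _distances(proposals, data_summary, S, R, "analytic", 0, rng)
        rows.append((S, R, int((d <= tolerance).sum())))
    table = pd.DataFrame(rows, columns=["S", "R", "accepted"])
    total = table["accepted"].sum()
    if total == 0:
        raise ValueError("no acceptances for any candidate; increase the tolerance")
    table["probability"] = table["accepted"] / total
    top = table["accepted"].max()
    tied = table.loc[table["accepted"] == top, ["S", "R"]]
    ties = tuple(map(tuple, tied.to_numpy())) if len(tied) > 1 else ()
    return ModelChoiceResult(
        table=table, tolerance=tolerance, n_proposals=n_proposals, seed=seed, ties=ties
    )


def posterior_summary(post: ABCPosterior) -> pd.DataFrame:
    """Per-parameter median and central 95% credible interval."""
    if post.n_accepted < 100:
        warnings.warn(
            f"only {post.n_accepted} accepted draws; posterior summaries are coarse",
            UserWarning, stacklevel=2,
        )
    med = np.median(post.draws, axis=0)
    lo, hi = np.percentile(post.draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"parameter": list(PARAM_NAMES), "median": med, "ci_low": lo, "ci_high": hi}
    )
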