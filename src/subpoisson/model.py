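"""Steady-state moment analysis of a multi-step gene expression model.

The reaction scheme describes constitutive transcription through a cycle of
``S`` sequential promoter states, export of nuclear mRNA to the cytoplasm, and
degradation through ``R`` sequential cytoplasmic intermediates::

    (U0 <-> U1)  U1 -> U2 -> ... -> US -> U1 + MN
    MN -> MC1 -> MC2 -> ... -> MCR -> 0

``U1..US`` are promoter states traversed before each synthesis event (rate
``k_A`` for each remodeling step, ``k_B`` for the final synthesis-triggering
step), ``MN`` is mature nuclear mRNA (exported at rate ``k_C``) and ``MC1..MCR``
are cytoplasmic degradation intermediates (each processed at rate ``k_D``).
An optional closed-chromatin state ``U0`` (switching rates ``k_open`` /
``k_close``) turns the ``S = 1`` special case into the classical two-state
telegraph model; ``S = 1`` without chromatin switching is the classical
single-rate-limiting-step constitutive model, whose mRNA counts are Poisson in
every compartment.

With ``S >= 2`` the wait times between synthesis events are hypoexponential
(narrower than exponential), which makes sub-Poissonian mRNA counts (Fano
factor < 1) possible.  Whether the cytoplasm is quieter or noisier than the
nucleus is controlled by the nuclear export rate: the two Fano factors cross at
a finite ``k_C`` (see :func:`export_crossover`).

All propensities are linear in the species counts, so the first- and
second-moment equations of the chemical master equation close exactly.  Because
exactly one promoter indicator is occupied at any time, one indicator is
eliminated via the conservation law and the remaining system is affine; means
solve a linear system and the stationary covariance solves a continuous
Lyapunov equation.  No approximation beyond floating point is involved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "ModelSpec",
    "ReactionNetwork",
    "MomentSolution",
    "MinFanoResult",
    "build_network",
    "steady_state_moments",
    "mean_expression",
    "min_fano",
    "export_crossover",
]

_TIME_UNITS = ("absolute", "effective_lifetime")


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of the reaction scheme.

    Parameters
    ----------
    S : int
        Number of sequential promoter states in the productive cycle (>= 1).
    R : int
        Number of sequential cytoplasmic degradation steps (>= 1).
    k_A : float
        Promoter remodeling rate for each ``U_i -> U_{i+1}``, ``i = 1..S-1``.
    k_B : float
        Promoter freeing / synthesis rate, ``U_S -> U_1 + MN``.
    k_C : float
        Nuclear export rate, ``MN -> MC1``.
    k_D : float
        Per-step cytoplasmic degradation rate for each ``MC_i -> MC_{i+1}``
        and ``MC_R -> 0``.  The *effective* degradation rate (inverse of the
        summed mean lifetimes of the intermediates) is ``k_D / R``.
    chromatin_on : tuple(float, float), optional
        ``(k_open, k_close)`` switching rates for the closed-chromatin state
        ``U0 -> U1`` / ``U1 -> U0``.  Absent means chromatin is always open.
    time_unit : {"absolute", "effective_lifetime"}
        In ``effective_lifetime`` units all rates are relative to the
        effective cytoplasmic degradation rate, which must then equal one
        (i.e. ``k_D == R``).
    """

    S: int
    R: int
    k_A: float
    k_B: float
    k_C: float
    k_D: float
    chromatin_on: tuple[float, float] | None = None
    time_unit: str = "absolute"

    def __post_init__(self) -> None:
        if int(self.S) != self.S or self.S < 1:
            raise ValueError(f"S must be an integer >= 1, got {self.S}")
        if int(self.R) != self.R or self.R < 1:
            raise ValueError(f"R must be an integer >= 1, got {self.R}")
        for name in ("k_A", "k_B", "k_C", "k_D"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be a finite positive rate, got {val}")
        if self.chromatin_on is not None:
            k_open, k_close = self.chromatin_on
            if not (k_open > 0 and k_close > 0):
                raise ValueError("chromatin switching rates must be positive")
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")
        if self.time_unit == "effective_lifetime":
            eff = self.k_D / self.R
            if abs(eff - 1.0) > 1e-9:
                raise ValueError(
                    "effective_lifetime units require the effective degradation "
                    f"rate k_D/R to equal 1 (got {eff!r}); set k_D = R"
                )

    @classmethod
    def effective(
        cls,
        S: int,
        R: int,
        k_A: float,
        k_B: float,
        k_C: float,
        chromatin_on: tuple[float, float] | None = None,
    ) -> "ModelSpec":
        """Spec in effective-lifetime units (``k_D`` fixed at ``R``)."""
        return cls(
            S=S, R=R, k_A=k_A, k_B=k_B, k_C=k_C, k_D=float(R),
            chromatin_on=chromatin_on, time_unit="effective_lifetime",
        )

    @property
    def effective_degradation_rate(self) -> float:
        return self.k_D / self.R

    @property
    def effective_lifetime(self) -> float:
        """Summed mean lifetime of the cytoplasmic intermediates."""
        return self.R / self.k_D

    def to_dict(self) -> dict:
        """Flat mapping for YAML/JSON serialization."""
        out = {
            "S": self.S, "R": self.R,
            "kA": self.k_A, "kB": self.k_B, "kC": self.k_C, "kD": self.k_D,
            "time_unit": self.time_unit,
        }
        if self.chromatin_on is not None:
            out["k_open"], out["k_close"] = self.chromatin_on
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        chromatin = None
        if "k_open" in d or "k_close" in d:
            chromatin = (float(d["k_open"]), float(d["k_close"]))
        return cls(
            S=int(d["S"]), R=int(d["R"]),
            k_A=float(d["kA"]), k_B=float(d["kB"]),
            k_C=float(d["kC"]), k_D=float(d["kD"]),
            chromatin_on=chromatin,
            time_unit=d.get("time_unit", "absolute"),
        )


@dataclass(frozen=True)
class ReactionNetwork:
    """Matrix form of the reaction scheme.

    Every propensity is ``rate * count(substrate)``, i.e. first order, so the
    moment equations close exactly.  Promoter indicators are conserved: the
    stoichiometry columns sum to zero over promoter-state species.
    """

    species: tuple[str, ...]
    stoichiometry: np.ndarray      # (n_species, n_reactions), int
    rate_constants: np.ndarray     # (n_reactions,)
    substrates: np.ndarray         # (n_reactions,) species index driving each propensity
    reaction_labels: tuple[str, ...]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.rate_constants)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def promoter_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.species) if s.startswith("U"))

    @property
    def nuclear_index(self) -> int:
        return self.species.index("MN")

    @property
    def cytoplasmic_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.species) if s.startswith("MC"))

    def initial_state(self) -> np.ndarray:
        """Default initial state: promoter in U1, no mRNA."""
        x0 = np.zeros(self.n_species, dtype=np.int64)
        x0[self.species_index("U1")] = 1
        return x0


def build_network(spec: ModelSpec) -> ReactionNetwork:
    """Assemble species list, stoichiometry and rates for a :class:`ModelSpec`.

    The network has ``(S - 1)`` remodeling reactions at ``k_A``, one synthesis
    reaction ``U_S -> U_1 + MN`` at ``k_B``, one export reaction at ``k_C``,
    ``R`` degradation-step reactions at ``k_D`` (the last to the empty set),
    plus two chromatin-switching reactions iff ``chromatin_on`` is present.
    """
    S, R = spec.S, spec.R
    species: list[str] = []
    if spec.chromatin_on is not None:
        species.append("U0")
    species += [f"U{i}" for i in range(1, S + 1)]
    species.append("MN")
    species += [f"MC{i}" for i in range(1, R + 1)]
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)

    cols: list[np.ndarray] = []
    rates: list[float] = []
    subs: list[int] = []
    labels: list[str] = []

    def add(label: str, rate: float, substrate: str, changes: list[tuple[str, int]]) -> None:
        # (species, delta) pairs, not a dict: for S == 1 the synthesis reaction
        # touches U1 twice (-1 substrate, +1 product) and the deltas must add.
        v = np.zeros(n, dtype=np.int64)
        for s, dv in changes:
            v[idx[s]] += dv
        cols.append(v)
        rates.append(rate)
        subs.append(idx[substrate])
        labels.append(label)

    if spec.chromatin_on is not None:
        k_open, k_close = spec.chromatin_on
        add("chromatin_open", k_open, "U0", [("U0", -1), ("U1", +1)])
        add("chromatin_close", k_close, "U1", [("U1", -1), ("U0", +1)])
    for i in range(1, S):
        add(f"remodel_{i}", spec.k_A, f"U{i}", [(f"U{i}", -1), (f"U{i + 1}", +1)])
    # U_S -> U_1 + MN; for S == 1 the promoter state is unchanged.
    add("synthesis", spec.k_B, f"U{S}", [(f"U{S}", -1), ("U1", +1), ("MN", +1)])
    add("export", spec.k_C, "MN", [("MN", -1), ("MC1", +1)])
    for i in range(1, R):
        add(f"decay_step_{i}", spec.k_D, f"MC{i}", [(f"MC{i}", -1), (f"MC{i + 1}", +1)])
    add(f"decay_step_{R}", spec.k_D, f"MC{R}", [(f"MC{R}", -1)])

    return ReactionNetwork(
        species=tuple(species),
        stoichiometry=np.column_stack(cols),
        rate_constants=np.asarray(rates, dtype=float),
        substrates=np.asarray(subs, dtype=np.int64),
        reaction_labels=tuple(labels),
    )


@dataclass(frozen=True)
class MomentSolution:
    """Exact steady-state first and second moments of the full state.

    ``second_moments`` is the covariance matrix over all species (promoter
    indicators included).  ``fano_cytoplasmic`` and ``cov_nuc_cyto`` refer to
    the *total* cytoplasmic count ``C = sum_i MC_i``, which is what smFISH
    measures (degradation intermediates are indistinguishable).
    """

    species: tuple[str, ...]
    means: np.ndarray
    second_moments: np.ndarray
    fano_nuclear: float
    fano_cytoplasmic: float
    cov_nuc_cyto: float

    @property
    def mean_nuclear(self) -> float:
        return float(self.means[self.species.index("MN")])

    @property
    def mean_cytoplasmic(self) -> float:
        cy = [i for i, s in enumerate(self.species) if s.startswith("MC")]
        return float(self.means[cy].sum())

    @property
    def var_nuclear(self) -> float:
        i = self.species.index("MN")
        return float(self.second_moments[i, i])

    @property
    def var_cytoplasmic(self) -> float:
        cy = [i for i, s in enumerate(self.species) if s.startswith("MC")]
        return float(self.second_moments[np.ix_(cy, cy)].sum())

    def to_frame(self):
        """Means and marginal variances as a DataFrame (delimited-text export)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "species": list(self.species),
                "mean": self.means,
                "variance": np.diag(self.second_moments),
            }
        )


def steady_state_moments(spec: ModelSpec) -> MomentSolution:
    """Solve the linear steady-state moment equations exactly.

    One promoter indicator (``U1``) is eliminated using the conservation law
    ``sum_i U_i = 1``; the reduced propensities are affine, the reduced drift
    matrix is Hurwitz, and the stationary covariance solves the Lyapunov
    equation ``A C + C A' + D = 0`` with ``D`` the diffusion matrix evaluated
    at the stationary means.
    """
    network = build_network(spec)
    return _moments_from_network(network)


def _moments_from_network(network: ReactionNetwork) -> MomentSolution:
    n = network.n_species
    promoters = list(network.promoter_indices)
    elim = network.species_index("U1")
    keep = [i for i in range(n) if i != elim]
    pos = {full: red for red, full in enumerate(keep)}
    other_promoters = [p for p in promoters if p != elim]
    m = len(keep)

    A = np.zeros((m, m))
    b = np.zeros(m)
    # per-reaction affine propensity a_j(y) = w_j . y + b_j on the reduced state
    W = np.zeros((network.n_reactions, m))
    b_j = np.zeros(network.n_reactions)
    V = network.stoichiometry[keep, :].astype(float)  # (m, n_reactions)
    for j in range(network.n_reactions):
        k = network.rate_constants[j]
        r = network.substrates[j]
        if r == elim:
            b_j[j] = k
            for p in other_promoters:
                W[j, pos[p]] -= k
        else:
            W[j, pos[r]] = k
        A += np.outer(V[:, j], W[j])
        b += V[:, j] * b_j[j]

    try:
        mu = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - valid specs are regular
        raise RuntimeError(
            "singular steady-state system; drift matrix:\n" f"{A!r}"
        ) from exc

    a_at_mu = W @ mu + b_j
    D = (V * a_at_mu) @ V.T
    C = linalg.solve_continuous_lyapunov(A, -D)
    C = 0.5 * (C + C.T)

    # Re-embed the eliminated indicator: U1 = 1 - sum(other promoters).
    means = np.empty(n)
    means[keep] = mu
    means[elim] = 1.0 - sum(mu[pos[p]] for p in other_promoters)
    cov = np.zeros((n, n))
    cov[np.ix_(keep, keep)] = C
    if other_promoters:
        rows = [pos[p] for p in other_promoters]
        cov[elim, keep] = -C[rows, :].sum(axis=0)
        cov[keep, elim] = cov[elim, keep]
        cov[elim, elim] = C[np.ix_(rows, rows)].sum()

    i_n = network.nuclear_index
    cyto = list(network.cytoplasmic_indices)
    mean_n = means[i_n]
    mean_c = means[cyto].sum()
    var_n = cov[i_n, i_n]
    var_c = cov[np.ix_(cyto, cyto)].sum()
    cov_nc = cov[i_n, cyto].sum()

    return MomentSolution(
        species=network.species,
        means=means,
        second_moments=cov,
        fano_nuclear=float(var_n / mean_n),
        fano_cytoplasmic=float(var_c / mean_c),
        cov_nuc_cyto=float(cov_nc),
    )


def mean_expression(spec: ModelSpec) -> tuple[float, float]:
    """Closed-form steady-state means for the chromatin-absent model.

    The promoter cycle is a renewal process with production rate
    ``lambda = 1 / ((S - 1)/k_A + 1/k_B)``; the means are ``lambda / k_C``
    (nuclear) and ``lambda * R / k_D`` (total cytoplasmic).  Serves as an
    independent check on :func:`steady_state_moments`.
    """
    if spec.chromatin_on is not None:
        raise ValueError("mean_expression supports only chromatin-absent specs")
    lam = 1.0 / ((spec.S - 1) / spec.k_A + 1.0 / spec.k_B)
    return lam / spec.k_C, lam * spec.R / spec.k_D


@dataclass(frozen=True)
class MinFanoResult:
    """Outcome of a multi-start Fano-factor minimization."""

    value: float
    rates: dict
    compartment: str
    converged: bool
    n_starts: int

    def __post_init__(self) -> None:
        if not self.converged:
            warnings.warn(
                "min_fano: optimizer did not report convergence from any start",
                RuntimeWarning,
                stacklevel=3,
            )


def _fano_of_rates(S: int, R: int, rates: np.ndarray, compartment: str) -> float:
    spec = ModelSpec.effective(S, R, k_A=rates[0], k_B=rates[1], k_C=rates[2])
    sol = steady_state_moments(spec)
    return sol.fano_nuclear if compartment == "nuclear" else sol.fano_cytoplasmic


def min_fano(
    S: int,
    R: int,
    compartment: str = "cytoplasmic",
    rate_bounds: tuple[tuple[float, float], ...] = ((1e-1, 1e3),) * 3,
    export_regime: float | None = None,
    n_starts: int = 12,
    seed: int = 0,
) -> MinFanoResult:
    """Minimize the steady-state Fano factor over ``(k_A, k_B, k_C)``.

    Works in effective-lifetime units (``k_D = R``).  ``export_regime`` pins
    the export rate: a finite value fixes ``k_C`` there, ``math.inf`` fixes it
    at the upper bound of its box (the fast-export limit), ``None`` leaves it
    free.  Multi-start Nelder-Mead on log10 rates; a result from a run where
    no start converged carries ``converged=False`` and raises a warning.
    """
    if compartment not in ("nuclear", "cytoplasmic"):
        raise ValueError("compartment must be 'nuclear' or 'cytoplasmic'")
    bounds = np.log10(np.asarray(rate_bounds, dtype=float))
    fixed_kc: float | None = None
    if export_regime is not None:
        fixed_kc = 10.0 ** bounds[2, 1] if math.isinf(export_regime) else float(export_regime)
    free = 2 if fixed_kc is not None else 3

    def objective(logr: np.ndarray) -> float:
        logr = np.clip(logr, bounds[:free, 0], bounds[:free, 1])
        r = 10.0 ** logr
        rates = np.array([r[0], r[1], fixed_kc]) if fixed_kc is not None else r
        return _fano_of_rates(S, R, rates, compartment)

    rng = np.random.default_rng(seed)
    best_val, best_x, converged = np.inf, None, False
    for _ in range(n_starts):
        x0 = rng.uniform(bounds[:free, 0], bounds[:free, 1])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 2000},
        )
        converged = converged or bool(res.success)
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, bounds[:free, 0], bounds[:free, 1])

    r = 10.0 ** best_x
    rates = {"kA": float(r[0]), "kB": float(r[1])}
    rates["kC"] = float(fixed_kc) if fixed_kc is not None else float(r[2])
    return MinFanoResult(
        value=best_val, rates=rates, compartment=compartment,
        converged=converged, n_starts=n_starts,
    )


def export_crossover(
    spec: ModelSpec,
    k_C_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
) -> float | None:
    """Export rate at which nuclear and cytoplasmic Fano factors are equal.

    Scans ``fano_cytoplasmic - fano_nuclear`` over ``k_C_grid`` (default
    log-spaced ``1e-2 .. 1e3``), brackets the first sign change and bisects on
    ``log10(k_C)`` to relative tolerance ``rtol``.  Below the crossover the
    cytoplasm is noisier than the nucleus; above it (the fast-export,
    sub-Poissonian regime) the cytoplasm is quieter.  Returns ``None`` when no
    sign change exists on the grid (e.g. ``S = 1``, where both Fano factors
    are identically 1).
    """
    if spec.chromatin_on is not None:
        raise ValueError("export_crossover supports only chromatin-absent specs")
    if k_C_grid is None:
        k_C_grid = np.logspace(-2, 3, 60)
    k_C_grid = np.sort(np.asarray(k_C_grid, dtype=float))

    def diff(kc: float) -> float:
        sol = steady_state_moments(replace(spec, k_C=kc))
        return sol.fano_cytoplasmic - sol.fano_nuclear

    vals = np.array([diff(kc) for kc in k_C_grid])
    sign = np.sign(vals)
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if change.size == 0:
        return None
    lo, hi = k_C_grid[change[0]], k_C_grid[change[0] + 1]
    root = optimize.brentq(
        lambda u: diff(10.0 ** u), math.log10(lo), math.log10(hi),
        xtol=rtol / math.log(10),
    )
    return float(10.0 ** root)
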