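"""Monod chemostat dynamics for interaction motifs and stability mapping.

Each motif code ([NCM][12][ab]) maps to one representative topology over a
state vector of two organism abundances, one or two primary resources, and
zero/one/two cross-fed metabolites:

* digit 1, 'b': both organisms consume resource alpha; digit 1, 'a': only
  organism 1 does.
* digit 2, 'a': organism 1 consumes alpha, organism 2 consumes beta;
  digit 2, 'b': organism 1 consumes alpha, organism 2 consumes both (and
  uses the product of the two Monod terms, the printed two-resource form).
* C adds one cross-fed metabolite produced by organism 1 and consumed by
  organism 2; M adds the reciprocal edge as well.

An organism's specific growth factor is the product Monod term over jointly
required primary resources and an additive Monod term for each cross-fed
metabolite it consumes (substitutable byproduct feeding); resource drains
and cross-fed production/consumption follow the printed chemostat balance,
with the inflow I an additive constant. A "classical" inflow mode
(D*(feed - m)) is available as an option.

Stability of a cell in the (mu_max1, mu_max2) grid means both abundances
exceed 0.05 g/L at t = 500 h.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

MOTIF_RE = re.compile(r"^[NCM][12][ab]$")

__all__ = [
    "ChemostatParams",
    "MotifTopology",
    "MotifStabilityMap",
    "build_motif_system",
    "simulate",
    "stability_map",
    "single_species_stability",
    "analytic_single_species_stable",
    "stable_fraction",
]


@dataclass(frozen=True)
class ChemostatParams:
    mu_max: tuple[float, float] = (0.5, 0.5)   # h^-1, grid axis 0..1
    dilution: float = 0.1                      # D, h^-1
    inflow: float = 0.1                        # I per primary resource (additive)
    half_sat: float = 0.05                     # k, g/L (all Monod terms)
    yield_ratio: float = 0.5                   # K, g nutrient / g cells
    secretion_rate: float = 0.1                # k_mtilde, h^-1
    crossfed_yield: float = 0.5                # K_mtilde,s
    initial_abundance: float = 0.1             # s_i(0), g/L
    initial_resource: float = 0.0              # m(0), g/L
    t_end: float = 500.0
    stability_threshold: float = 0.05          # g/L at t_end
    classical_inflow: bool = False             # use D*(feed - m) instead of I

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        for name in (
            "inflow",
            "half_sat",
            "yield_ratio",
            "secretion_rate",
            "crossfed_yield",
            "initial_abundance",
            "initial_resource",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MotifTopology:
    motif_code: str
    n_resources: int
    org_resources: tuple[tuple[int, ...], tuple[int, ...]]  # primary indices per org
    product_form: tuple[bool, bool]          # org uses product of its primary terms
    edges: tuple[tuple[int, int], ...]       # (giver, receiver) per crossfed met

    @property
    def n_states(self) -> int:
        return 2 + self.n_resources + len(self.edges)

    @property
    def state_names(self) -> tuple[str, ...]:
        res = tuple(f"m_{'ab'[r]}" for r in range(self.n_resources))
        mts = tuple(f"mt_{g + 1}" for g, _ in self.edges)
        return ("s_1", "s_2") + res + mts


def motif_topology(motif_code: str) -> MotifTopology:
    if not MOTIF_RE.match(motif_code or ""):
        raise ValueError(f"unknown motif code {motif_code!r}")
    iclass, digit, comp = motif_code[0], int(motif_code[1]), motif_code[2]
    if digit == 1:
        n_resources = 1
        if comp == "b":
            org_resources = ((0,), (0,))
        else:
            org_resources = ((0,), ())
    else:
        n_resources = 2
        if comp == "a":
            org_resources = ((0,), (1,))
        else:
            org_resources = ((0,), (0, 1))
    if iclass == "N":
        edges: tuple[tuple[int, int], ...] = ()
    elif iclass == "C":
        edges = ((0, 1),)
    else:
        edges = ((0, 1), (1, 0))
    product_form = tuple(len(r) > 1 for r in org_resources)
    return MotifTopology(motif_code, n_resources, org_resources, product_form, edges)


class MotifSystem:
    """ODE right-hand side for one motif, vectorizable across a mu grid."""

    def __init__(self, topology: MotifTopology, params: ChemostatParams):
        self.topology = topology
        self.params = params

    @property
    def y0(self) -> np.ndarray:
        p, t = self.params, self.topology
        return np.array(
            [p.initial_abundance] * 2
            + [p.initial_resource] * t.n_resources
            + [0.0] * len(t.edges)
        )

    def rhs(self, t, y, mu=None):
        """dy/dt; ``y`` may be (n_states,) or (n_states, ncells) with mu arrays."""
        del t
        p, topo = self.params, self.topology
        if mu is None:
            mu = p.mu_max
        y = np.maximum(y, 0.0)
        s = [y[0], y[1]]
        nr = topo.n_resources
        m = [y[2 + r] for r in range(nr)]
        mt = [y[2 + nr + e] for e in range(len(topo.edges))]
        k, D = p.half_sat, p.dilution

        monod_m = [mr / (k + mr) for mr in m]
        monod_mt = [me / (k + me) for me in mt]

        factors = []
        for i in (0, 1):
            res = topo.org_resources[i]
            if topo.product_form[i]:
                f = np.prod([monod_m[r] for r in res], axis=0)
            elif res:
                f = sum(monod_m[r] for r in res)
            else:
                f = 0.0
            for e, (_, recv) in enumerate(topo.edges):
                if recv == i:
                    f = f + monod_mt[e]
            factors.append(f)

        ds = [s[i] * (mu[i] * factors[i] - D) for i in (0, 1)]

        dm = []
        for r in range(nr):
            drain = sum(
                s[i] / p.yield_ratio * mu[i] * monod_m[r]
                for i in (0, 1)
                if r in topo.org_resources[i]
            )
            if p.classical_inflow:
                supply = D * (p.inflow / D - m[r])
                dm.append(supply - drain)
            else:
                dm.append(p.inflow - drain - D * m[r])

        dmt = []
        for e, (giver, recv) in enumerate(topo.edges):
            dmt.append(
                p.secretion_rate * s[giver]
                - s[recv] / p.crossfed_yield * mu[recv] * monod_mt[e]
                - D * mt[e]
            )

        return np.array(ds + dm + dmt)


def build_motif_system(motif_code: str, params: ChemostatParams) -> MotifSystem:
    return MotifSystem(motif_topology(motif_code), params)


def simulate(
    system: MotifSystem,
    params: ChemostatParams | None = None,
    n_out: int = 201,
):
    """Integrate one trajectory to t_end (stiff-capable LSODA, rtol 1e-6).

    Returns ``(t, Y)`` with Y of shape (n_out, n_states); negative values are
    clipped to zero.
    """
    params = params or system.params
    if params is not system.params:
        system = MotifSystem(system.topology, params)
    y0 = system.y0
    if not np.all(np.isfinite(y0)):
        raise ValueError("non-finite initial state")
    sol = solve_ivp(
        system.rhs,
        (0.0, params.t_end),
        y0,
        method="LSODA",
        rtol=1e-6,
        atol=1e-9,
        t_eval=np.linspace(0.0, params.t_end, n_out),
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, np.maximum(sol.y.T, 0.0)


@dataclass
class MotifStabilityMap:
    motif_code: str
    mu_grid: np.ndarray                 # shared axis for both organisms
    stable: np.ndarray                  # bool, stable[i, j] at (mu1_i, mu2_j)
    params: ChemostatParams = field(default_factory=ChemostatParams)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("mu1\\mu2\t" + "\t".join(f"{v:.6g}" for v in self.mu_grid) + "\n")
            for i, mu1 in enumerate(self.mu_grid):
                fh.write(
                    f"{mu1:.6g}\t"
                    + "\t".join(str(int(v)) for v in self.stable[i])
                    + "\n"
                )
        return path


def _integrate_grid(
    system: MotifSystem, mu1: np.ndarray, mu2: np.ndarray, dt: float = 0.05
) -> np.ndarray:
    """Fixed-step RK4 across all grid cells simultaneously.

    All cells share smooth, bounded dynamics at the default parameter scale,
    for which dt = 0.05 h is well inside the RK4 stability region; states are
    clipped at zero after every step.
    """
    p = system.params
    n_steps = int(np.ceil(p.t_end / dt))
    h = p.t_end / n_steps
    ncells = mu1.size
    y = np.tile(system.y0[:, None], (1, ncells))
    mu = (mu1, mu2)
    f = system.rhs
    for _ in range(n_steps):
        k1 = f(0.0, y, mu)
        k2 = f(0.0, y + 0.5 * h * k1, mu)
        k3 = f(0.0, y + 0.5 * h * k2, mu)
        k4 = f(0.0, y + h * k3, mu)
        y = np.maximum(y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return y


def stability_map(
    motif_code: str,
    params: ChemostatParams | None = None,
    grid_n: int = 51,
    mu_range: tuple[float, float] = (0.0, 1.0),
) -> MotifStabilityMap:
    """Boolean stability grid over (mu_max1, mu_max2) in [0, 1]^2."""
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    params = params or ChemostatParams()
    system = build_motif_system(motif_code, params)
    grid = np.linspace(mu_range[0], mu_range[1], grid_n)
    MU1, MU2 = np.meshgrid(grid, grid, indexing="ij")
    y_end = _integrate_grid(system, MU1.ravel(), MU2.ravel())
    thr = params.stability_threshold
    stable = ((y_end[0] > thr) & (y_end[1] > thr)).reshape(grid_n, grid_n)
    return MotifStabilityMap(motif_code, grid, stable, params)


def stable_fraction(m: MotifStabilityMap) -> float:
    return float(np.mean(m.stable))


# ---------------------------------------------------------------------------
# single-species reference


class _SingleSystem(MotifSystem):
    """One organism on one resource; organism 2 absent (mu2 pinned to 0)."""


def single_species_stability(
    mu_grid: np.ndarray, params: ChemostatParams | None = None
) -> np.ndarray:
    """Simulated persistence (s > threshold at t_end) for a lone consumer."""
    params = params or ChemostatParams()
    system = build_motif_system("N1a", params)  # org2 consumes nothing
    mu = np.asarray(mu_grid, dtype=float)
    y_end = _integrate_grid(system, mu, np.zeros_like(mu))
    return y_end[0] > params.stability_threshold


def analytic_single_species_stable(
    mu: float, params: ChemostatParams | None = None
) -> bool:
    """Closed-form washout criterion for one Monod consumer in a chemostat.

    Persistence needs the growth rate at the consumer-free resource level
    m_sup = I/D to exceed D, and the steady-state abundance
    s* = K (I - D lambda)/D (break-even concentration lambda = D k/(mu - D))
    to clear the stability threshold.
    """
    p = params or ChemostatParams()
    D, k, K, I = p.dilution, p.half_sat, p.yield_ratio, p.inflow
    m_sup = I / D
    if mu <= D or mu * m_sup / (k + m_sup) <= D:
        return False
    lam = D * k / (mu - D)
    s_star = K * (I - D * lam) / D
    return s_star > p.stability_threshold
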