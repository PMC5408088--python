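"""Configuration types and loading.

Internal unit conventions, used everywhere in the package:

* length   -- micrometres (um)
* time     -- seconds (s)
* mass     -- picograms (pg)
* pressure -- pascals (Pa)

Diffusion coefficients are therefore um^2/s internally; config files state
them in m^2/s (the unit the vasculogenesis literature uses) and
:func:`load_config` converts at the boundary (1 m^2/s = 1e12 um^2/s).
Volumetric flow is um^3/s and concentrations are mass per pixel area
(pg/um^2 on the 2D grid).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

M2S_TO_UM2S = 1.0e12

#: densest possible packing of equal disks in the plane
CLOSE_PACKING_FRACTION = math.pi / math.sqrt(12.0)


class ConfigError(ValueError):
    """Raised when a configuration file or value violates the schema."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass
class ChemoParams:
    """Parameters of the chemoattractant / chemotaxis model (Phase I).

    Two chemoattractant species share one diffusion coefficient ``D_c`` and
    differ only in decay rate: the vascular-cell species decays fast
    (``beta_v``, steep short-range gradients around nascent cords) and the
    circulatory-cell species decays slowly (``beta_c``, a long-range gradient
    that pulls the network onto the source/sink columns).  Secretion follows
    Monod kinetics in the (non-depleting) substrate ``N_c0`` with
    half-saturation ``k`` and maximal specific rate ``mu_c``.  The chemotactic
    force on a cell is the saturating response
    ``lambda_ * [C+/(1 + beta_sat*C+) - C-/(1 + beta_sat*C-)]``
    sampled across the cell along a random unit direction, applied only when
    positive.  Adhesion is a short-range linear-ramp attraction between
    vascular cells.
    """

    D_c: float = 0.1                 # um^2/s (1e-13 m^2/s)
    mu_c: float = 0.01               # 1/s
    k: float = 0.5                   # conc, half-saturation for secretion
    N_c0: float = 1.0                # conc, secretion substrate (held constant)
    beta_v: float = 0.1 / 144.0      # 1/s, fast decay  -> range ~12 um
    beta_c: float = 2.0e-5           # 1/s, slow decay  -> range ~70 um
    lambda_: float = 2000.0          # force units per (saturated) conc diff
    beta_sat: float = 50.0           # 1/conc; deep saturation ~ log-sensing
    adhesion_strength: float = 0.3   # force units at zero gap
    adhesion_range: float = 2.0      # um, gap beyond which adhesion vanishes
    separate_fields: bool = False    # respond to the two fields separately
    lambda_long_ratio: float = 0.1   # response weight of the long-range field
    contact_inhibition: bool = True  # chemotaxis only into vascular-free directions
    contact_margin: float = 0.5      # um, gap below which a neighbour blocks
    contact_cone_cos: float = 0.5    # block if direction within acos() of neighbour
    n_directions: int = 6            # random protrusion directions per step

    def __post_init__(self) -> None:
        _require(self.D_c > 0, "D_c", "must be > 0")
        _require(self.beta_v > 0 and self.beta_c > 0, "beta_v/beta_c", "must be > 0")
        _require(
            self.beta_v > self.beta_c,
            "beta_v",
            "vascular decay must exceed circulatory decay (beta_v > beta_c)",
        )
        _require(self.lambda_ >= 0, "lambda_", "must be >= 0")
        _require(self.beta_sat >= 0, "beta_sat", "must be >= 0")
        _require(self.mu_c >= 0, "mu_c", "must be >= 0")
        _require(self.k > 0, "k", "must be > 0")
        _require(self.N_c0 >= 0, "N_c0", "must be >= 0")
        _require(self.adhesion_strength >= 0, "adhesion_strength", "must be >= 0")
        _require(self.adhesion_range > 0, "adhesion_range", "must be > 0")


@dataclass
class FlowParams:
    """Pressure boundary condition and fluid viscosity for the pipe network.

    ``delta_P`` is the pressure difference imposed between the source and the
    sink supernode.  ``eta`` defaults to the dynamic viscosity of water at
    25 C.
    """

    delta_P: float = 1000.0   # Pa
    eta: float = 8.9e-4       # Pa*s

    def __post_init__(self) -> None:
        _require(self.delta_P > 0, "delta_P", "must be > 0")
        _require(self.eta > 0, "eta", "must be > 0")


@dataclass
class FactoryParams:
    """Kinetics of the running factory (Phase III).

    Vessel-wall nutrient delivery:  rho_n * 2*pi*r * Q/(k_out+Q) * k_l/(k_l+N)
    Product synthesis per producer: mu_p * N/(N+k_p) * k_i/(X+k_i) * M_p
    Vessel-wall product uptake:     rho_p * 2*pi*r * Q/(k_in+Q) * X/(k_p+X)
    Nutrient consumption:           mu_n * N/(N+k_p) * k_i/(k_i+X) * M_p

    All four rates share the Michaelis constant ``k_p`` and inhibition
    constant ``k_i``.  Values are calibrated (the vanillin-producer system
    they emulate publishes no directly transferable constants) so that, at the
    default geometry, producers adjacent to flowing vessels activate while the
    interior of large lacunae starves; every value is config-overridable.
    """

    rho_n: float = 0.3          # pg/(um*s), nutrient transfer constant
    rho_p: float = 0.3          # pg/(um*s), product transfer constant
    k_out: float = 2.0e5        # um^3/s, flow half-saturation (delivery)
    k_in: float = 2.0e5         # um^3/s, flow half-saturation (uptake)
    k_l: float = 1.0            # conc, nutrient half-saturation (delivery)
    mu_p: float = 2.0           # 1/s, product synthesis rate
    mu_n: float = 28.0          # 1/s, nutrient consumption rate
    k_p: float = 0.2            # conc, Michaelis constant
    k_i: float = 0.25           # conc, product-inhibition constant
    M_p: float = 1.0            # pg, producer biomass
    D_p: float = 20.0           # um^2/s (2e-11 m^2/s), diffusion of N and X
    activation_threshold: float = 0.02   # conc; default k_p/10
    dt: float = 0.0             # s; 0 -> use the explicit stability bound
    steady_tol: float = 0.02    # relative throughput drift per window
    production_window: float = 7200.0    # s, accounting window at steady state
    max_sim_time: float = 36000.0        # s, give up on steady state after this

    def __post_init__(self) -> None:
        for name in (
            "rho_n", "rho_p", "k_out", "k_in", "k_l", "mu_p", "mu_n",
            "k_p", "k_i", "M_p", "D_p",
        ):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.activation_threshold > 0, "activation_threshold", "must be > 0")
        _require(self.production_window > 0, "production_window", "must be > 0")
        _require(self.steady_tol > 0, "steady_tol", "must be > 0")
        _require(self.dt >= 0, "dt", "must be >= 0")


@dataclass
class ConvergenceSpec:
    """Termination criterion of the morphogenesis loop.

    The loop stops when the largest per-step cell displacement stays below
    ``eps_move`` and the relative chemoattractant field change below
    ``eps_field`` for ``patience`` consecutive mechanical steps, or at
    ``max_steps``.
    """

    eps_move: float = 0.05    # um
    eps_field: float = 1.0e-3
    patience: int = 10
    max_steps: int = 5000

    def __post_init__(self) -> None:
        _require(self.eps_move > 0, "eps_move", "must be > 0")
        _require(self.eps_field > 0, "eps_field", "must be > 0")
        _require(self.patience > 0, "patience", "must be > 0")
        _require(self.max_steps > 0, "max_steps", "must be > 0")


@dataclass
class SimulationConfig:
    """Full description of one vascular-factory simulation.

    Geometry: a ``domain_width`` x ``domain_height`` um rectangle with two
    fixed circulatory columns (left = source, right = sink) hugging the
    vertical edges, and ``n_interior_cells`` particles seeded uniformly at
    random between them, each vascular with probability ``vascular_fraction``
    and a producer otherwise.
    """

    domain_height: float = 516.0      # um
    domain_width: float = 1028.0      # um
    grid_resolution: float = 1.0      # um per pixel
    n_circulatory: int = 780          # total; split into two columns
    n_interior_cells: int = 24000
    vascular_fraction: float = 0.30
    cell_radius: float = 2.3          # um
    cell_biomass_vascular: float = 1.0   # pg (M_v, also circulatory)
    cell_biomass_producer: float = 1.0   # pg (M_p)
    chemo_params: ChemoParams = field(default_factory=ChemoParams)
    flow_params: FlowParams = field(default_factory=FlowParams)
    factory_params: FactoryParams = field(default_factory=FactoryParams)
    dt_mech: float = 1.0              # s, mechanical step
    dt_solute: float = 0.0            # s; 0 -> use the stability bound
    mobility: float = 1.0             # um/(force*s), overdamped conversion
    step_cap_factor: float = 1.0      # max displacement per step, in cell radii
    mask_dilation: float = 1.25       # um added to radii when rasterizing
    mask_closing: int = 2             # 3x3 binary-closing passes on the mask
    min_spur_length: float = 0.0      # um; 0 -> 2*cell_radius
    seed: int = 0
    convergence: ConvergenceSpec = field(default_factory=ConvergenceSpec)

    def __post_init__(self) -> None:
        _require(self.domain_height > 0, "domain_height", "must be > 0")
        _require(self.domain_width > 0, "domain_width", "must be > 0")
        _require(self.grid_resolution > 0, "grid_resolution", "must be > 0")
        _require(
            self.grid_resolution <= self.cell_radius,
            "grid_resolution",
            "must be <= cell_radius (a cell must span at least one pixel)",
        )
        _require(0.0 <= self.vascular_fraction <= 1.0, "vascular_fraction",
                 "must lie in [0, 1]")
        _require(self.n_circulatory >= 0, "n_circulatory", "must be >= 0")
        _require(self.n_circulatory % 2 == 0, "n_circulatory",
                 "must be even (two equal columns)")
        _require(self.n_interior_cells >= 0, "n_interior_cells", "must be >= 0")
        _require(self.cell_radius > 0, "cell_radius", "must be > 0")
        _require(self.cell_biomass_vascular > 0, "cell_biomass_vascular", "must be > 0")
        _require(self.cell_biomass_producer > 0, "cell_biomass_producer", "must be > 0")
        _require(self.dt_mech > 0, "dt_mech", "must be > 0")
        _require(self.dt_solute >= 0, "dt_solute", "must be >= 0")
        _require(self.mobility > 0, "mobility", "must be > 0")
        _require(self.mask_dilation >= 0, "mask_dilation", "must be >= 0")
        _require(self.min_spur_length >= 0, "min_spur_length", "must be >= 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the solute grid; row 0 at the bottom."""
        h = self.grid_resolution
        return (int(round(self.domain_height / h)), int(round(self.domain_width / h)))

    @property
    def interior_x_range(self) -> tuple[float, float]:
        """x interval available to interior cells (excludes the columns)."""
        d = 2.0 * self.cell_radius
        return (d, self.domain_width - d)

    @property
    def spur_threshold(self) -> float:
        return self.min_spur_length if self.min_spur_length > 0 else 2.0 * self.cell_radius

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (for run manifests)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# profiles

def reference_profile(**overrides) -> SimulationConfig:
    """Reference-scale configuration: 516 x 1028 um, 24,000 interior cells."""
    return SimulationConfig(**overrides)


def scaled_profile(**overrides) -> SimulationConfig:
    """Desk-scale configuration: 258 x 258 um, 3000 interior cells.

    Circulatory columns keep the reference linear density (390 cells per
    516 um column -> 195 per 258 um column).  The morphogenesis step budget
    is shortened accordingly; chemotaxis noise never lets the displacement
    criterion trigger exactly, so max_steps is the effective run length.
    """
    defaults = dict(
        domain_height=258.0,
        domain_width=258.0,
        n_circulatory=390,
        n_interior_cells=3000,
        factory_params=FactoryParams(production_window=30.0, max_sim_time=300.0),
        convergence=ConvergenceSpec(max_steps=300),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# config files

_DIFFUSION_KEYS = {"D_c": "chemo_params", "D_p": "factory_params"}

_SECTION_TYPES = {
    "chemo_params": ChemoParams,
    "flow_params": FlowParams,
    "factory_params": FactoryParams,
    "convergence": ConvergenceSpec,
}


def _build_section(name: str, cls, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{name}: unknown key(s) {sorted(unknown)}")
    kwargs = dict(raw)
    # diffusion coefficients are given in m^2/s in files; internal unit um^2/s
    for key in ("D_c", "D_p"):
        if key in kwargs:
            kwargs[key] = float(kwargs[key]) * M2S_TO_UM2S
    return cls(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    The file is a single mapping whose keys are ``SimulationConfig`` field
    names; the nested sections ``chemo_params``, ``flow_params``,
    ``factory_params`` and ``convergence`` are mappings of their own field
    names.  Unknown keys are an error (catches typos).  ``D_c`` and ``D_p``
    are read in m^2/s and converted to um^2/s.  A ``profile`` key
    (``reference`` | ``scaled``) selects the base defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config file must be a mapping")

    profile = raw.pop("profile", "reference")
    if profile not in ("reference", "scaled"):
        raise ConfigError(f"profile: must be 'reference' or 'scaled', got {profile!r}")
    base = reference_profile() if profile == "reference" else scaled_profile()

    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)}")

    kwargs = dataclasses.asdict(base)
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            merged = dataclasses.asdict(getattr(base, key))
            # file sections override defaults field-by-field
            section = _build_section(key, _SECTION_TYPES[key], value)
            merged.update(
                {f.name: getattr(section, f.name)
                 for f in dataclasses.fields(section) if f.name in value}
            )
            kwargs[key] = merged
        else:
            kwargs[key] = value
    for name, cls in _SECTION_TYPES.items():
        if isinstance(kwargs[name], dict):
            kwargs[name] = cls(**kwargs[name])
    return SimulationConfig(**kwargs)
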