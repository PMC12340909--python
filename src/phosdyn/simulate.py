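"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its config and seed: random streams
are derived from ``(seed, operation name)`` so adding one generator never
perturbs another's draws.

The HDX forward model is a two-state EX2 ensemble: a residue with
protection factor PF exchanges at ``k_int/PF`` in the closed state and at
the intrinsic rate ``k_int`` in the open state, and the observed rate is
the population-weighted mixture

    k_eff = p_open * k_int + (1 - p_open) * k_int / PF.

Occupancy after labelling time t in a bath of deuterium fraction ``d2o``
is ``d2o * (1 - exp(-k_eff * t))``.  Centroid masses then add the
back-exchange-scaled sum of residue occupancies to the undeuterated
monoisotopic mass.  EX1 bimodality is deliberately out of scope: the
downstream analysis is centroid-based and could not represent it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import hdx
from .errors import ConfigError

_AMINO = "ACDEFGHIKLMNQRSTVWY"  # proline added separately where wanted

#: Default labelling time course, seconds.
DEFAULT_TIMEPOINTS = (0, 30, 120, 480, 960, 1920, 3840, 7680)


def _rng(seed: int, op: str) -> np.random.Generator:
    """Per-operation random stream derived from (seed, operation name)."""
    tag = int.from_bytes(op.encode()[:4].ljust(4, b"\0"), "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

@dataclass
class HdxSimConfig:
    """Study design for a synthetic HDX-MS experiment.

    ``protection`` maps each state to either a scalar PF applied uniformly
    or a {residue (1-based): PF} mapping on top of ``base_protection``.
    ``open_fraction`` is each state's open-ensemble weight.  The same
    peptide pool is emitted for every state; pass ``peptides`` as explicit
    (start, end) windows to control the pool exactly, otherwise
    ``n_peptides`` random windows are drawn.
    """

    protein_length: int
    sequence: str
    states: Sequence[str]
    protection: Mapping[str, float | Mapping[int, float]]
    open_fraction: Mapping[str, float] = field(default_factory=dict)
    base_protection: float = 1.0
    k_intrinsic: float = 1.0
    d2o_fraction: float = 0.9
    back_exchange: float = 0.85
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    centroid_noise_sd: float = 0.0
    n_peptides: int = 40
    peptide_length_range: tuple[int, int] = (5, 15)
    peptides: Sequence[tuple[int, int]] | None = None
    exclude_second: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.protein_length:
            raise ConfigError("sequence length must equal protein_length")
        tps = list(self.timepoints)
        if tps != sorted(tps) or 0 not in tps:
            raise ConfigError("timepoints must be ascending and include 0")
        if not 0 < self.d2o_fraction <= 1:
            raise ConfigError("d2o_fraction must be in (0, 1]")
        if not 0 < self.back_exchange <= 1:
            raise ConfigError("back_exchange must be in (0, 1]")
        if self.centroid_noise_sd < 0:
            raise ConfigError("centroid_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for st in self.states:
            if st not in self.protection:
                raise ConfigError(f"no protection map for state {st!r}")
            p = self.open_fraction.get(st, 0.0)
            if not 0 <= p <= 1:
                raise ConfigError(f"open_fraction for {st!r} must be in [0, 1]")

    def protection_array(self, state: str) -> np.ndarray:
        """Per-residue PF array (index 0 unused) for one state."""
        pf = np.full(self.protein_length + 1, float(self.base_protection))
        entry = self.protection[state]
        if isinstance(entry, Mapping):
            for res, val in entry.items():
                if not 1 <= int(res) <= self.protein_length:
                    raise ConfigError(f"protection residue {res} outside protein")
                pf[int(res)] = float(val)
        else:
            pf[:] = float(entry)
        if np.any(pf < 1):
            raise ConfigError("all protection factors must be >= 1")
        return pf


def simulate_residue_exchange(pf, p_open, k_int, t, d2o):
    """Deuterium occupancy of one residue under the two-state EX2 model.

    Vectorised over any argument; returns ``d2o * (1 - exp(-k_eff * t))``
    with ``k_eff = p_open*k_int + (1-p_open)*k_int/pf``.
    """
    pf = np.asarray(pf, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(pf < 1):
        raise ConfigError("protection factor must be >= 1")
    if np.any(t < 0):
        raise ConfigError("time must be >= 0")
    k_eff = p_open * k_int + (1.0 - p_open) * k_int / pf
    return d2o * (1.0 - np.exp(-k_eff * t))


def _make_pool(cfg: HdxSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    if cfg.peptides is not None:
        windows = [(int(s), int(e)) for s, e in cfg.peptides]
    else:
        lo, hi = cfg.peptide_length_range
        windows = []
        for _ in range(cfg.n_peptides):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, cfg.protein_length - length + 2))
            windows.append((start, start + length - 1))
    rows = []
    for i, (s, e) in enumerate(windows, start=1):
        if not (1 <= s <= e <= cfg.protein_length):
            raise ConfigError(f"peptide window [{s}, {e}] outside [1, {cfg.protein_length}]")
        rows.append(
            (f"p{i:04d}", cfg.sequence[s - 1 : e], s, e, int(rng.integers(1, 4)))
        )
    return pd.DataFrame(rows, columns=hdx.POOL_COLUMNS)


def simulate_hdx_dataset(cfg: HdxSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (peptide pool, centroid table) pair for all states.

    Centroid at (state, t, replicate) is the undeuterated monoisotopic
    mass plus ``back_exchange x sum of exchangeable-residue occupancies``
    plus Gaussian noise; full-D control rows carry occupancy ``d2o`` at
    every exchangeable amide, and undeuterated rows the bare mass.
    """
    rng = _rng(cfg.seed, "hdx")
    pool = _make_pool(cfg, rng)
    pf = {st: cfg.protection_array(st) for st in cfg.states}
    p_open = {st: cfg.open_fraction.get(st, 0.0) for st in cfg.states}

    rows = []

    def emit(peptide_id, state, t, rep, mass):
        noise = rng.normal(0.0, cfg.centroid_noise_sd) if cfg.centroid_noise_sd else 0.0
        rows.append((peptide_id, state, t, rep, mass + noise))

    for pep in pool.itertuples(index=False):
        m0 = hdx.peptide_monoisotopic_mass(pep.sequence)
        positions = np.array(
            hdx.exchangeable_positions(pep.sequence, pep.start, cfg.exclude_second),
            dtype=int,
        )
        for rep in range(1, cfg.n_replicates + 1):
            emit(pep.id, hdx.UNDEUTERATED, np.nan, rep, m0)
            full = cfg.back_exchange * len(positions) * cfg.d2o_fraction
            emit(pep.id, hdx.FULL_D, np.nan, rep, m0 + full)
        for state in cfg.states:
            for t in cfg.timepoints:
                occ = simulate_residue_exchange(
                    pf[state][positions] if len(positions) else np.empty(0),
                    p_open[state],
                    cfg.k_intrinsic,
                    float(t),
                    cfg.d2o_fraction,
                )
                uptake = cfg.back_exchange * float(np.sum(occ))
                for rep in range(1, cfg.n_replicates + 1):
                    emit(pep.id, state, float(t), rep, m0 + uptake)
    centroids = pd.DataFrame(rows, columns=hdx.CENTROID_COLUMNS)
    return pool, centroids


def random_protein_sequence(length: int, seed: int = 0, proline_rate: float = 0.04) -> str:
    """Random amino-acid sequence with a controllable proline rate."""
    rng = _rng(seed, "seq")
    letters = [
        "P" if rng.random() < proline_rate else _AMINO[rng.integers(len(_AMINO))]
        for _ in range(length)
    ]
    return "".join(letters)


# ---------------------------------------------------------------------------
# phosphosite tables
# ---------------------------------------------------------------------------

@dataclass
class PhosphositeSimConfig:
    """Design of a synthetic curated-phosphosite table.

    Observation counts follow a heavy-tailed lognormal
    (``obs_mu``/``obs_sigma`` on the log scale); literature support is
    Poisson with mean ``lit_rate`` per MS observation.  Planted hotspots
    are (protein accession, site label, target count) triples whose
    targets must exceed the background distribution's upper decile.
    """

    n_sites: int
    n_proteins: int
    planted_hotspots: Sequence[tuple[str, str, int]] = ()
    obs_mu: float = 1.0
    obs_sigma: float = 1.2
    lit_rate: float = 0.05
    organism: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_sites >= self.n_proteins >= 1:
            raise ConfigError("need n_sites >= n_proteins >= 1")


def simulate_phosphosite_table(cfg: PhosphositeSimConfig) -> pd.DataFrame:
    """Emit a curated-style phosphosite table with planted hotspots.

    Columns: GENE, PROTEIN, ACC_ID, MOD_RSD, ORGANISM, LT_LIT, MS_LIT,
    MS_CST.  Planted rows receive their target observation counts split
    between MS_LIT and MS_CST.
    """
    rng = _rng(cfg.seed, "phos")
    acc = [f"P{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    genes = {a: f"GENE{i}" for i, a in enumerate(acc, start=1)}
    known = set(acc)
    for prot, _site, _cnt in cfg.planted_hotspots:
        if prot not in known:
            raise ConfigError(f"planted hotspot references unknown protein {prot!r}")

    protein = rng.choice(acc, size=cfg.n_sites)
    residue = rng.choice(list("STY"), size=cfg.n_sites, p=[0.55, 0.25, 0.20])
    position = rng.integers(1, 2000, size=cfg.n_sites)
    obs = np.ceil(rng.lognormal(cfg.obs_mu, cfg.obs_sigma, size=cfg.n_sites)).astype(int)
    obs = np.maximum(obs, 0)

    upper_decile = float(np.quantile(obs, 0.9))
    planted = list(cfg.planted_hotspots)
    for _prot, _site, cnt in planted:
        if cnt <= upper_decile:
            raise ConfigError(
                f"planted count {cnt} does not exceed background upper decile {upper_decile:g}"
            )
    # overwrite the first len(planted) rows with the planted sites
    if len(planted) > cfg.n_sites:
        raise ConfigError("more planted hotspots than rows")
    rows = []
    for i in range(cfg.n_sites):
        if i < len(planted):
            prot, site_label, cnt = planted[i]
            total = int(cnt)
        else:
            prot = protein[i]
            site_label = f"{residue[i]}{position[i]}-p"
            total = int(obs[i])
        ms_lit = int(rng.binomial(total, 0.5))
        ms_cst = total - ms_lit
        lt_lit = int(rng.poisson(cfg.lit_rate * total)) if cfg.lit_rate > 0 else 0
        rows.append(
            (genes[prot], genes[prot], prot, site_label, cfg.organism, lt_lit, ms_lit, ms_cst)
        )
    return pd.DataFrame(
        rows,
        columns=["GENE", "PROTEIN", "ACC_ID", "MOD_RSD", "ORGANISM", "LT_LIT", "MS_LIT", "MS_CST"],
    )


# ---------------------------------------------------------------------------
# enzyme kinetics, activation, melt curves
# ---------------------------------------------------------------------------

@dataclass
class KineticsSimConfig:
    """Generator settings for rate tables and melt curves.

    ``vmax`` and ``km`` parameterise the Michaelis-Menten velocity law;
    ``noise_sd`` is multiplicative (fraction of the true rate) for rate
    tables and additive (fraction of amplitude) for melt curves.  Melt
    curves are sampled on a 25-99 degC grid with midpoint ``tm`` and width
    ``melt_slope``; an optional post-peak decay mimics dye release after
    full unfolding.
    """

    vmax: float = 0.15
    km: float = 50.0
    enzyme_conc: float = 0.005
    substrate_grid: Sequence[float] = (0, 7.8, 15.6, 31.2, 62.5, 125, 250, 500, 1000, 2000)
    noise_sd: float = 0.0
    tm: float = 55.0
    melt_slope: float = 1.5
    amplitude: float = 1000.0
    baseline: float = 50.0
    decay: bool = False
    decay_onset: float = 8.0
    decay_tau: float = 15.0
    temp_range: tuple[float, float] = (25.0, 99.0)
    temp_step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0 or self.enzyme_conc <= 0:
            raise ConfigError("vmax, km and enzyme_conc must be > 0")
        if len(self.substrate_grid) == 0:
            raise ConfigError("substrate grid must not be empty")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_mm_rates(cfg: KineticsSimConfig) -> pd.DataFrame:
    """Velocity table v = Vmax*S/(Km+S) * (1 + eps), eps ~ N(0, noise_sd)."""
    rng = _rng(cfg.seed, "mm")
    s = np.asarray(cfg.substrate_grid, dtype=float)
    if np.any(s < 0):
        raise ConfigError("substrate concentrations must be >= 0")
    v = cfg.vmax * s / (cfg.km + s)
    if cfg.noise_sd > 0:
        v = v * (1.0 + rng.normal(0.0, cfg.noise_sd, size=s.shape))
    return pd.DataFrame({"substrate_uM": s, "velocity": v})


def simulate_melt_curve(cfg: KineticsSimConfig) -> pd.DataFrame:
    """Thermal-shift fluorescence curve with optional post-peak decay.

    An ascending logistic with midpoint ``tm`` and width ``melt_slope``;
    when ``decay`` is set, fluorescence beyond ``tm + decay_onset`` decays
    exponentially with constant ``decay_tau`` (SYPRO-orange-like), so the
    global maximum sits after the midpoint.
    """
    rng = _rng(cfg.seed, "melt")
    lo, hi = cfg.temp_range
    temps = np.arange(lo, hi + cfg.temp_step / 2, cfg.temp_step)
    f = cfg.baseline + cfg.amplitude / (1.0 + np.exp(-(temps - cfg.tm) / cfg.melt_slope))
    if cfg.decay:
        onset = cfg.tm + cfg.decay_onset
        f = np.where(temps > onset, f * np.exp(-(temps - onset) / cfg.decay_tau), f)
    if cfg.noise_sd > 0:
        f = f + rng.normal(0.0, cfg.noise_sd * cfg.amplitude, size=f.shape)
    return pd.DataFrame({"temperature_C": temps, "fluorescence": f})


def simulate_activation_curve(
    baseline: float,
    max_fold: float,
    ec50_uM: float,
    concentrations: Sequence[float] = (0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hyperbolic activator titration including the zero-activator baseline."""
    rng = _rng(seed, "act")
    c = np.asarray(concentrations, dtype=float)
    signal = baseline * (1.0 + (max_fold - 1.0) * c / (ec50_uM + c))
    if noise_sd > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=c.shape))
    return pd.DataFrame({"activator_uM": c, "signal": signal})


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_conformers(
    n_atoms: int,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate pair (P, Q): Q is a rigid transform of P plus jitter.

    P is a random-walk chain (Ca-like 3.8 A steps); the transform defaults
    to a random rotation plus a random translation drawn from the same
    seeded stream.
    """
    if n_atoms < 1:
        raise ConfigError("n_atoms must be >= 1")
    rng = _rng(seed, "conf")
    steps = rng.normal(size=(n_atoms, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    p = np.cumsum(3.8 * steps, axis=0)
    if rotation is None:
        rotation = random_rotation(rng)
    if translation is None:
        translation = rng.normal(0.0, 10.0, size=3)
    q = p @ np.asarray(rotation).T + np.asarray(translation)
    if jitter_sd > 0:
        q = q + rng.normal(0.0, jitter_sd, size=q.shape)
    return p, q


def simulate_hinge_conformers(
    n_atoms: int = 60,
    hinge: int = 30,
    angle_deg: float = 60.0,
    jitter_sd: float = 0.3,
    from_state: str = "open",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(closed_ref, open_ref, model) toy for conformer classification.

    The open reference rotates all atoms past the hinge atom by
    ``angle_deg`` about a fixed axis through the hinge point; the model is
    a jittered copy of the reference named by ``from_state``.
    """
    if from_state not in ("open", "closed"):
        raise ConfigError("from_state must be 'open' or 'closed'")
    rng = _rng(seed, "hing")
    steps = rng.normal(size=(n_atoms, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    closed = np.cumsum(3.8 * steps, axis=0)
    theta = np.deg2rad(angle_deg)
    axis = np.array([0.0, 0.0, 1.0])
    k = axis
    def rot(v):  # Rodrigues about z through the hinge point
        pivot = closed[hinge]
        x = v - pivot
        return (
            x * np.cos(theta)
            + np.cross(k, x) * np.sin(theta)
            + k * np.dot(x, k) * (1 - np.cos(theta))
        ) + pivot
    open_ = closed.copy()
    for i in range(hinge, n_atoms):
        open_[i] = rot(closed[i])
    source = open_ if from_state == "open" else closed
    model = source + rng.normal(0.0, jitter_sd, size=source.shape)
    return closed, open_, model
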