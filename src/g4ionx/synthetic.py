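"""Synthetic-data generators for every input the pipeline consumes.

Each generator emits the statistical structure its downstream analysis
assumes — three-state binding fractions for titrations, offset exponentials
for kinetic traces, r**-6 intensities with linear buildup for NOESY tables,
and two-state sigmoids for melting curves — so the whole pipeline can be run
and tested without any experimental download.  Named presets encode the
published study conditions for the Tel23 quadruplex (stepwise constants,
conversion time constants, HDX/hybridization means, melting midpoints);
everything is deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomRef,
    G4Sequence,
    KineticTrace,
    MeltingCurve,
    NOESYPeak,
    PeakTable,
    STANDARD_MIXING_TIMES,
    TitrationSeries,
    tel23,
)
from .exchange import ExchangeModelParams, _fractions
from .noe import REFERENCE_DISTANCE

# --- Tel23 study constants --------------------------------------------------

#: Stepwise exchange constants for the G22 imino proton (per molar).
TEL23_K1 = 59.7
TEL23_K2 = 2.7

#: Real-time CD conversion at 265 nm: fast/slow time constants (s) and the
#: fast-phase amplitude fraction.
CD_CONVERSION_TAUS = (80.0, 930.0)
CD_CONVERSION_F1 = 0.89

#: HDX unfolding time constants (min) of the central-tetrad imino protons.
HDX_TAU = {"na": 14.0, "na_k_simultaneous": 136.0}

#: Hybridization-trap unfolding time constants (min).
HYB_TAU = {"na": 17.0, "na_k_simultaneous": 127.0, "na_k_pretreat": 130.0}

#: CD melting midpoints at 295 nm (deg C).
TM = {"na": 59.3, "k": 68.9}

#: Distance-class moments (mean angstroms, sd) behind the grouped NOE stats.
DISTANCE_CLASSES = {
    ("H8-H1 intra-tetrad", "na"): (5.1, 0.2),
    ("H1-H1", "na"): (4.9, 0.6),
    ("H8-H1 intra-tetrad", "k"): (4.6, 0.4),
    ("H1-H1", "k"): (4.3, 0.3),
    ("H8-H1 intra-tetrad", "na_k_mixed"): (4.3, 0.4),
    ("H1-H1", "na_k_mixed"): (4.0, 0.3),
}

#: Intra-residue H1'-H8 distances emitted for syn and anti guanines.
SYN_DISTANCE = 2.5
ANTI_DISTANCE = 3.7

SCENARIOS = (
    "tel23_titration",
    "tel23_hdx_na",
    "tel23_hdx_nak",
    "tel23_hybridization",
    "tel23_cd_conversion",
    "tel23_noesy_na",
    "tel23_noesy_k",
    "tel23_melting_na",
    "tel23_melting_k",
)

CANONICAL_TOPOLOGIES = (
    "parallel propeller",
    "antiparallel basket",
    "antiparallel chair",
    "hybrid-I (3+1)",
    "hybrid-II (3+1)",
)


@dataclass
class ScenarioConfig:
    """Seedable configuration shared by all generators.

    ``noise_sd`` is expressed as a fraction of the signal amplitude.  Grid
    parameters that are None fall back to the scenario's preset grid.
    """

    seed: int = 0
    scenario: str = "tel23_titration"
    noise_sd: float = 0.02
    concentrations_mM: np.ndarray | None = None
    times: np.ndarray | None = None
    temperatures: np.ndarray | None = None
    mixing_times: tuple[float, ...] = STANDARD_MIXING_TIMES
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------


def gen_titration(
    config: ScenarioConfig,
    residue: AtomRef | None = None,
    k1_multiplier: float = 1.0,
) -> tuple[TitrationSeries, TitrationSeries]:
    """Paired Na+-form decay and K+-form rise titration series.

    Intensities are the three-state species fractions fa and fc on the
    concentration grid plus Gaussian noise of sd ``noise_sd``.  The default
    constants are the Tel23 G22 values; ``k1_multiplier`` scales K1 to
    emulate residues (bottom tetrad) that lag the exchange.
    """
    K1 = config.params.get("K1", TEL23_K1) * k1_multiplier
    K2 = config.params.get("K2", TEL23_K2)
    conc = config.concentrations_mM
    if conc is None:
        conc = np.arange(0.0, 150.0 + 1e-9, 5.0)
    conc = np.asarray(conc, dtype=float)
    x_molar = conc * 1e-3
    fa, _, fc = _fractions(K1, K2, x_molar)
    rng = config.rng()
    if config.noise_sd > 0:
        fa = fa + rng.normal(0.0, config.noise_sd, fa.shape)
        fc = fc + rng.normal(0.0, config.noise_sd, fc.shape)
    if residue is None:
        residue = AtomRef(22, "H1", "G")
    na = TitrationSeries(
        residue=residue,
        form_tracked="na_form",
        points=list(zip(conc.tolist(), fa.tolist())),
        conc_unit="mM",
        normalization={"generator": {"K1": K1, "K2": K2, "seed": config.seed}},
    )
    k = TitrationSeries(
        residue=residue,
        form_tracked="k_form",
        points=list(zip(conc.tolist(), fc.tolist())),
        conc_unit="mM",
        normalization={"generator": {"K1": K1, "K2": K2, "seed": config.seed}},
    )
    return na, k


def exchange_params() -> ExchangeModelParams:
    """The preset stepwise constants as model parameters (per molar)."""
    return ExchangeModelParams(TEL23_K1, TEL23_K2, conc_unit="M")


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------


def gen_kinetic_trace(config: ScenarioConfig) -> KineticTrace | tuple[KineticTrace, KineticTrace]:
    """Exponential kinetic trace(s) for the named scenario.

    * ``tel23_hdx_na`` / ``tel23_hdx_nak`` — mono-exponential imino-signal
      decays with the HDX condition constants (14 min / 136 min).
    * ``tel23_cd_conversion`` — rising bi-exponential 265 nm CD trace with
      the 80 s / 930 s constants and an 89% fast-phase amplitude.
    * ``tel23_hybridization`` — a paired (G4 imino decay, Watson-Crick rise)
      sharing one time constant; condition set by ``params['condition']``.
    """
    s = config.scenario
    rng = config.rng()
    if s == "tel23_hdx_na" or s == "tel23_hdx_nak":
        tau = config.params.get(
            "tau", HDX_TAU["na" if s.endswith("_na") else "na_k_simultaneous"]
        )
        t = config.times
        if t is None:
            t = np.arange(0.0, 120.0 + 1e-9, 5.0) if s.endswith("_na") else np.arange(
                0.0, 600.0 + 1e-9, 10.0
            )
        sig = np.exp(-np.asarray(t, float) / tau)
        sig = sig + rng.normal(0.0, config.noise_sd, sig.shape)
        return KineticTrace(t, sig, kind="hdx", time_unit="min", label=s)
    if s == "tel23_cd_conversion":
        tau1, tau2 = config.params.get("taus", CD_CONVERSION_TAUS)
        f1 = config.params.get("f1", CD_CONVERSION_F1)
        t = config.times
        if t is None:
            t = np.arange(0.0, 3600.0 + 1e-9, 5.0)
        t = np.asarray(t, float)
        sig = 1.0 - (f1 * np.exp(-t / tau1) + (1 - f1) * np.exp(-t / tau2))
        sig = sig + rng.normal(0.0, config.noise_sd, sig.shape)
        return KineticTrace(
            t, sig, kind="cd_conversion", time_unit="s", label="cd_265nm"
        )
    if s == "tel23_hybridization":
        condition = config.params.get("condition", "na_k_simultaneous")
        tau = config.params.get("tau", HYB_TAU[condition])
        t = config.times
        if t is None:
            t = np.arange(0.0, 600.0 + 1e-9, 10.0)
        t = np.asarray(t, float)
        decay = np.exp(-t / tau) + rng.normal(0.0, config.noise_sd, t.shape)
        rise = 1.0 - np.exp(-t / tau) + rng.normal(0.0, config.noise_sd, t.shape)
        return (
            KineticTrace(t, decay, kind="hybridization", time_unit="min", label="g4_imino"),
            KineticTrace(t, rise, kind="hybridization", time_unit="min", label="wc_imino"),
        )
    raise ValueError(f"unknown kinetic scenario {s!r}; choose from {SCENARIOS}")


# ---------------------------------------------------------------------------
# NOESY peak tables
# ---------------------------------------------------------------------------


def _peak_rows(
    distances: list[tuple[AtomRef, AtomRef, float]],
    mixing_times: tuple[float, ...],
    condition: str,
    noise_sd: float,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> list[NOESYPeak]:
    """Linear buildup intensities obeying the r**-6 law.

    The reference distance pair gets intensity ``scale * t_mix``; every other
    pair is scaled by (r_ref / r)**6.
    """
    peaks = []
    for a, b, r in distances:
        base = scale * (REFERENCE_DISTANCE / r) ** 6
        for tm in mixing_times:
            inten = base * tm
            if noise_sd > 0:
                inten = max(0.0, inten * (1.0 + rng.normal(0.0, noise_sd)))
            peaks.append(NOESYPeak(a, b, tm, inten, condition))
    return peaks


# Canonical fold definitions on the Tel23 scaffold.  Each fold is given by
# the cyclic order of tracts around the tetrad square, per-tract strand
# directions, and the per-layer rotational direction of the H1->H8 cycle
# (+1 follows the square order, -1 runs against it).
_FOLDS: dict[str, dict] = {
    "parallel propeller": {
        "square": (0, 1, 2, 3),
        "orient": ("up", "up", "up", "up"),
        "cycle_dir": (+1, +1, +1),
        "syn_rule": lambda layer, orient: False,  # all anti
    },
    "antiparallel basket": {
        "square": (0, 1, 3, 2),
        "orient": ("up", "down", "up", "down"),
        "cycle_dir": (+1, +1, +1),
        "syn_rule": lambda layer, orient: orient == "down",
    },
    "antiparallel chair": {
        "square": (0, 1, 2, 3),
        "orient": ("up", "down", "up", "down"),
        "cycle_dir": (+1, +1, +1),
        "syn_rule": lambda layer, orient: orient == "down",
    },
    "hybrid-I (3+1)": {
        "square": (0, 3, 2, 1),
        "orient": ("up", "up", "down", "up"),
        "cycle_dir": (+1, -1, -1),  # top cycle runs against the lower two
        "syn_rule": lambda layer, orient: (
            orient == "up" if layer == 0 else orient == "down"
        ),
    },
    "hybrid-II (3+1)": {
        "square": (0, 1, 2, 3),
        "orient": ("up", "down", "up", "up"),
        "cycle_dir": (+1, +1, +1),
        "syn_rule": lambda layer, orient: orient == "down",
    },
}


def fold_layers(label: str, seq: G4Sequence) -> list[tuple[int, int, int, int]]:
    """Residues of each tetrad layer (top to bottom), ordered by tract."""
    fold = _FOLDS[label]
    layers = []
    for layer in range(3):
        members = []
        for t, tract in enumerate(seq.g_tracts):
            pos = layer if fold["orient"][t] == "up" else 2 - layer
            members.append(tract[pos])
        layers.append(tuple(members))
    return layers


def fold_tetrad_cycles(label: str, seq: G4Sequence) -> list[tuple[int, int, int, int]]:
    """Directed H1->H8 cycles (top to bottom) for a canonical fold."""
    fold = _FOLDS[label]
    layers = fold_layers(label, seq)
    cycles = []
    for layer, members in enumerate(layers):
        by_tract = dict(zip(range(4), members))
        order = [by_tract[t] for t in fold["square"]]
        if fold["cycle_dir"][layer] < 0:
            order = [order[0]] + order[1:][::-1]
        cycles.append(tuple(order))
    return cycles


def fold_syn_residues(label: str, seq: G4Sequence) -> set[int]:
    fold = _FOLDS[label]
    syn = set()
    for layer, members in enumerate(fold_layers(label, seq)):
        for t, ridx in enumerate(members):
            if fold["syn_rule"](layer, fold["orient"][t]):
                syn.add(ridx)
    return syn


def gen_noesy_peaks(
    config: ScenarioConfig,
    distances: list[tuple[AtomRef, AtomRef, float]] | None = None,
) -> PeakTable:
    """Synthetic assigned NOESY peak table.

    With an explicit ``distances`` list, emits r**-6 linear-buildup
    intensities (plus the thymine H6-CH3 reference pair).  With a scenario
    of the form ``canonical_topology:<label>``, emits the full connectivity
    pattern of that fold: intra-tetrad H1->H8 cycles, inter-tetrad H1-H1
    stacking contacts, and intra-residue H1'-H8 peaks encoding the syn/anti
    pattern.  ``tel23_noesy_na`` / ``tel23_noesy_k`` draw per-class distances
    around the published class means for the grouped statistics.
    """
    seq: G4Sequence = config.params.get("seq", tel23())
    rng = config.rng()
    cond = config.params.get("condition", "na")
    ref_t = _reference_thymine(seq)
    ref = [(AtomRef(ref_t, "H6", "T"), AtomRef(ref_t, "CH3", "T"), REFERENCE_DISTANCE)]

    if distances is not None:
        rows = _peak_rows(
            ref + list(distances), config.mixing_times, cond, config.noise_sd, rng
        )
        return PeakTable(rows, source="synthetic")

    s = config.scenario
    if s.startswith("canonical_topology:"):
        label = s.split(":", 1)[1]
        if label not in _FOLDS:
            raise ValueError(
                f"unknown topology label {label!r}; available: {sorted(_FOLDS)}"
            )
        dists: list[tuple[AtomRef, AtomRef, float]] = []
        cycles = fold_tetrad_cycles(label, seq)
        for cyc in cycles:
            for i in range(4):
                donor, acceptor = cyc[i], cyc[(i + 1) % 4]
                dists.append(
                    (AtomRef(donor, "H1", "G"), AtomRef(acceptor, "H8", "G"), 4.0)
                )
        # inter-tetrad stacking H1-H1 contacts along each tract
        for upper, lower in zip(cycles, cycles[1:]):
            for t in range(4):
                ru = _member_in_tract(upper, t, seq)
                rl = _member_in_tract(lower, t, seq)
                dists.append((AtomRef(ru, "H1", "G"), AtomRef(rl, "H1", "G"), 4.9))
        syn = fold_syn_residues(label, seq)
        for tract in seq.g_tracts:
            for ridx in tract:
                r = SYN_DISTANCE if ridx in syn else ANTI_DISTANCE
                dists.append((AtomRef(ridx, "H1'", "G"), AtomRef(ridx, "H8", "G"), r))
        rows = _peak_rows(ref + dists, config.mixing_times, cond, config.noise_sd, rng)
        return PeakTable(rows, source=f"synthetic:{label}")

    if s in ("tel23_noesy_na", "tel23_noesy_k"):
        cond = "na" if s.endswith("_na") else "k"
        n_per_class = int(config.params.get("n_per_class", 12))
        dists = []
        counter = 0
        for (pair_class, c), (mean, sd) in DISTANCE_CLASSES.items():
            if c != cond:
                continue
            draws = rng.normal(mean, sd, n_per_class)
            for val in draws:
                a, b = _synthetic_pair(pair_class, counter, seq)
                counter += 1
                dists.append((a, b, float(max(val, 1.5))))
        rows = _peak_rows(ref + dists, config.mixing_times, cond, config.noise_sd, rng)
        return PeakTable(rows, source=f"synthetic:{s}")

    raise ValueError(f"unknown NOESY scenario {s!r}")


def _reference_thymine(seq: G4Sequence) -> int:
    for i, base in seq.residues:
        if base == "T":
            return i
    raise ValueError("sequence has no thymine for the H6-CH3 reference")


def _member_in_tract(cycle: tuple[int, ...], tract: int, seq: G4Sequence) -> int:
    for r in cycle:
        if seq.tract_of(r) == tract:
            return r
    raise ValueError(f"cycle {cycle} has no member in tract {tract}")


def _synthetic_pair(pair_class: str, i: int, seq: G4Sequence) -> tuple[AtomRef, AtomRef]:
    """Distinct G-tract atom pairs to carry drawn distances of a given class."""
    gs = [r for tract in seq.g_tracts for r in tract]
    a = gs[i % len(gs)]
    b = gs[(i + 3) % len(gs)]
    if a == b:
        b = gs[(i + 4) % len(gs)]
    if pair_class == "H8-H1 intra-tetrad":
        return AtomRef(a, "H1", "G"), AtomRef(b, "H8", "G")
    if pair_class == "H1-H1":
        return AtomRef(a, "H1", "G"), AtomRef(b, "H1", "G")
    raise ValueError(pair_class)


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------


def gen_melting_curve(config: ScenarioConfig) -> MeltingCurve:
    """Two-state sigmoid melting curve with linear baselines plus noise.

    Presets ``tel23_melting_na`` / ``tel23_melting_k`` use the published
    295 nm midpoints (59.3 / 68.9 deg C); the default logistic width of
    3 deg C gives the ~12-15 deg C transition breadth typical of quadruplex
    CD melts.
    """
    s = config.scenario
    if s == "tel23_melting_na":
        tm_default = TM["na"]
    elif s == "tel23_melting_k":
        tm_default = TM["k"]
    else:
        tm_default = config.params.get("tm")
        if tm_default is None:
            raise ValueError(f"unknown melting scenario {s!r} and no 'tm' parameter")
    tm = config.params.get("tm", tm_default)
    width = config.params.get("width", 3.0)
    amp = config.params.get("amplitude", 10.0)  # mdeg, folded minus unfolded
    bf = config.params.get("baseline_folded_slope", -0.01)
    bu = config.params.get("baseline_unfolded_slope", -0.005)
    temp = config.temperatures
    if temp is None:
        temp = np.arange(25.0, 95.0 + 1e-9, 0.5)
    temp = np.asarray(temp, dtype=float)
    if not temp[0] <= tm <= temp[-1]:
        import warnings

        warnings.warn(f"melting midpoint {tm} outside temperature grid", stacklevel=2)
    alpha = 1.0 / (1.0 + np.exp((tm - temp) / width))
    folded = amp + bf * (temp - temp[0])
    unfolded = 1.0 + bu * (temp - temp[0])
    theta = folded * (1 - alpha) + unfolded * alpha
    rng = config.rng()
    if config.noise_sd > 0:
        theta = theta + rng.normal(0.0, config.noise_sd * abs(amp), theta.shape)
    return MeltingCurve(temperature=temp, ellipticity=theta, wavelength_nm=295.0)
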