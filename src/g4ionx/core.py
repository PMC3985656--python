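"""Shared domain types and file I/O for G-quadruplex NMR/CD analyses.

The objects here are the common currency of the package: a guanine-tract
annotated DNA sequence, atom references, NOESY cross-peak tables,
cation-titration series, kinetic traces and CD melting curves.  Readers and
writers use plain text formats (whitespace-delimited peak lists in the style
of Sparky assignment exports, CSV with headers for everything tabular) so
that synthetic and real data flow through the same code paths.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger("g4ionx")

#: Closed vocabulary of proton labels handled by the package.
ATOM_VOCAB = ("H1", "H8", "H1'", "CH3", "H6")

#: Mixing times (ms) of the standard exchangeable-proton NOE buildup series.
STANDARD_MIXING_TIMES = (50.0, 100.0, 150.0, 200.0)

#: Sample-condition labels: pure Na+, pure K+, or Na+ form after K+ addition.
CONDITIONS = ("na", "k", "na_k_mixed")


class FormatError(ValueError):
    """A file or token could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class DegenerateSeriesError(ValueError):
    """A titration series carries no usable signal (e.g. all-constant)."""


# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class G4Sequence:
    """A DNA sequence with its runs of >=2 consecutive guanines annotated.

    Residues are 1-based ``(index, base)`` pairs with contiguous indices, the
    numbering convention used throughout G4 NMR work (e.g. G3..G23 for
    Tel23).  ``g_tracts`` holds the guanine tracts in 5'->3' order; each is a
    tuple of residue indices.
    """

    residues: tuple[tuple[int, str], ...]
    g_tracts: tuple[tuple[int, ...], ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("empty sequence")
        idx = [i for i, _ in self.residues]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValidationError("residue indices must be contiguous and increasing")
        for i, base in self.residues:
            if base not in "ACGT":
                raise ValidationError(f"invalid base {base!r} at residue {i}")
        tracts: list[tuple[int, ...]] = []
        run: list[int] = []
        for i, base in self.residues:
            if base == "G":
                run.append(i)
            else:
                if len(run) >= 2:
                    tracts.append(tuple(run))
                run = []
        if len(run) >= 2:
            tracts.append(tuple(run))
        object.__setattr__(self, "g_tracts", tuple(tracts))

    @classmethod
    def from_string(cls, seq: str, start: int = 1) -> "G4Sequence":
        return cls(tuple((start + i, b) for i, b in enumerate(seq.upper())))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_index(self) -> int:
        return self.residues[0][0]

    def base(self, index: int) -> str:
        off = index - self.first_index
        if not 0 <= off < len(self.residues):
            raise ValidationError(f"residue index {index} outside sequence")
        return self.residues[off][1]

    def tract_of(self, index: int) -> int | None:
        """0-based tract number containing residue ``index``, or None."""
        for t, members in enumerate(self.g_tracts):
            if index in members:
                return t
        return None

    def tract_position(self, index: int) -> int | None:
        """0-based position of residue within its tract (5'->3'), or None."""
        t = self.tract_of(index)
        if t is None:
            return None
        return self.g_tracts[t].index(index)


def tel23() -> G4Sequence:
    """The 23-nt human telomeric sequence d[TAGGG(TTAGGG)3] ('Tel23')."""
    return G4Sequence.from_string("TAGGGTTAGGGTTAGGGTTAGGG")


# ---------------------------------------------------------------------------
# Atoms and peaks
# ---------------------------------------------------------------------------

_ATOM_TOKEN = re.compile(r"^([ACGT])(\d+)(H1'|CH3|H8|H6|H1)$")


@dataclass(frozen=True, order=True)
class AtomRef:
    """A single proton: residue index plus atom label (H1, H8, H1', CH3, H6)."""

    residue_index: int
    atom: str
    base: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.atom not in ATOM_VOCAB:
            raise ValidationError(f"unknown atom label {self.atom!r}")
        if self.residue_index < 1:
            raise ValidationError("residue_index must be >= 1")

    @classmethod
    def parse(cls, token: str) -> "AtomRef":
        m = _ATOM_TOKEN.match(token)
        if m is None:
            raise FormatError(f"unparseable atom token {token!r}")
        base, idx, atom = m.groups()
        return cls(int(idx), atom, base)

    def token(self, seq: G4Sequence | None = None) -> str:
        base = self.base
        if seq is not None:
            base = seq.base(self.residue_index)
        if base is None:
            raise ValidationError(
                f"cannot format atom {self!r}: base unknown and no sequence given"
            )
        return f"{base}{self.residue_index}{self.atom}"


@dataclass(frozen=True)
class NOESYPeak:
    """An assigned NOESY cross-peak at one mixing time.

    The atom pair is stored canonically (sorted by residue index then atom
    label) so that "G21H8-G3H1" and "G3H1-G21H8" are the same peak.  The
    imino->aromatic direction used for tetrad connectivity is recovered from
    the atom labels, not from storage order.
    """

    a: AtomRef
    b: AtomRef
    mixing_time: float
    intensity: float
    condition: str = "na"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(f"negative intensity {self.intensity}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if (self.a.residue_index, self.a.atom) > (self.b.residue_index, self.b.atom):
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    @property
    def pair(self) -> tuple[tuple[int, str], tuple[int, str]]:
        return ((self.a.residue_index, self.a.atom), (self.b.residue_index, self.b.atom))

    @property
    def nonstandard_mixing_time(self) -> bool:
        return self.mixing_time not in STANDARD_MIXING_TIMES

    @property
    def atoms(self) -> frozenset[str]:
        return frozenset((self.a.atom, self.b.atom))

    def h1_to_h8(self) -> tuple[int, int] | None:
        """Directed (imino residue, aromatic residue) if this is an H1-H8 peak."""
        if {self.a.atom, self.b.atom} != {"H1", "H8"}:
            return None
        if self.a.atom == "H1":
            return (self.a.residue_index, self.b.residue_index)
        return (self.b.residue_index, self.a.residue_index)


@dataclass
class PeakTable:
    """A collection of assigned NOESY peaks from one source."""

    peaks: list[NOESYPeak]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for p in self.peaks:
            key = (p.pair, p.mixing_time, p.condition)
            if key in seen:
                raise ValidationError(f"duplicate peak row {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def select(
        self,
        atoms: set[str] | frozenset[str] | None = None,
        condition: str | None = None,
        mixing_time: float | None = None,
    ) -> list[NOESYPeak]:
        out = self.peaks
        if atoms is not None:
            out = [p for p in out if p.atoms == frozenset(atoms)]
        if condition is not None:
            out = [p for p in out if p.condition == condition]
        if mixing_time is not None:
            out = [p for p in out if p.mixing_time == mixing_time]
        return list(out)

    def buildup_groups(
        self, condition: str | None = None
    ) -> dict[tuple, list[NOESYPeak]]:
        """Group peaks by (pair, condition) into per-pair buildup series."""
        groups: dict[tuple, list[NOESYPeak]] = {}
        for p in self.peaks:
            if condition is not None and p.condition != condition:
                continue
            groups.setdefault((p.pair, p.condition), []).append(p)
        for v in groups.values():
            v.sort(key=lambda p: p.mixing_time)
        return groups


def read_peak_list(path: str | Path, seq: G4Sequence | None = None) -> PeakTable:
    """Read a whitespace-delimited assigned peak list.

    Each data line holds four columns: an assignment token such as
    ``G3H1-G21H8``, the mixing time in ms, the intensity, and a condition
    label (``na``, ``k`` or ``na_k_mixed``).  Lines starting with ``#`` and
    blank lines are skipped.  Malformed lines raise a :class:`FormatError`
    naming the line number and offending token.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks: list[NOESYPeak] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        assign, mt_s, inten_s, cond = parts
        if "-" not in assign:
            raise FormatError(f"{path}:{lineno}: unparseable assignment {assign!r}")
        tok_a, tok_b = assign.split("-", 1)
        try:
            a = AtomRef.parse(tok_a)
            b = AtomRef.parse(tok_b)
        except FormatError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from None
        try:
            mt = float(mt_s)
            inten = float(inten_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad numeric field") from None
        if inten < 0:
            raise ValidationError(f"{path}:{lineno}: negative intensity {inten}")
        if seq is not None:
            for ref in (a, b):
                if ref.base is not None and seq.base(ref.residue_index) != ref.base:
                    raise ValidationError(
                        f"{path}:{lineno}: residue {ref.residue_index} is "
                        f"{seq.base(ref.residue_index)}, token says {ref.base}"
                    )
        peaks.append(NOESYPeak(a, b, mt, inten, cond))
    if not peaks:
        logger.warning("peak list %s contained no data lines", path)
        warnings.warn(f"peak list {path} is empty", stacklevel=2)
    return PeakTable(peaks, source=str(path))


def write_peak_list(table: PeakTable, path: str | Path, seq: G4Sequence | None = None) -> None:
    """Write a peak table in the format consumed by :func:`read_peak_list`."""
    path = Path(path)
    lines = ["# assignment mixing_time_ms intensity condition"]
    for p in table.peaks:
        lines.append(
            f"{p.a.token(seq)}-{p.b.token(seq)} {p.mixing_time!r} {p.intensity!r} {p.condition}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular series
# ---------------------------------------------------------------------------


@dataclass
class TitrationSeries:
    """Per-residue normalized imino intensity vs added cation concentration."""

    residue: AtomRef
    form_tracked: str  # "na_form" | "k_form"
    points: list[tuple[float, float]]
    conc_unit: str = "mM"
    normalization: dict | None = None

    def __post_init__(self) -> None:
        if self.form_tracked not in ("na_form", "k_form"):
            raise ValidationError(f"unknown form {self.form_tracked!r}")
        conc = [c for c, _ in self.points]
        if any(c < 0 for c in conc):
            raise ValidationError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValidationError("concentrations must be strictly increasing")

    @property
    def conc(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.points], dtype=float)

    def conc_molar(self) -> np.ndarray:
        scale = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6}.get(self.conc_unit)
        if scale is None:
            raise ValidationError(f"unknown concentration unit {self.conc_unit!r}")
        return self.conc * scale


@dataclass
class KineticTrace:
    """A time/signal trace: HDX decay, hybridization decay/rise, or CD conversion."""

    times: np.ndarray
    signal: np.ndarray
    kind: str = "hdx"  # hdx | hybridization | cd_conversion
    time_unit: str = "min"
    dead_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.kind not in ("hdx", "hybridization", "cd_conversion"):
            raise ValidationError(f"unknown trace kind {self.kind!r}")
        if self.times.shape != self.signal.shape:
            raise ValidationError("times and signal must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if len(self.times) < 5:
            raise ValidationError("at least 5 points required")

    def after_dead_time(self) -> tuple[np.ndarray, np.ndarray]:
        keep = self.times >= self.dead_time
        return self.times[keep], self.signal[keep]


@dataclass
class MeltingCurve:
    """CD ellipticity (mdeg) vs temperature (deg C), single wavelength."""

    temperature: np.ndarray
    ellipticity: np.ndarray
    wavelength_nm: float = 295.0

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperature.shape != self.ellipticity.shape:
            raise ValidationError("temperature and ellipticity must match in length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValidationError("temperature must be strictly increasing")
        if self.temperature.min() < 0 or self.temperature.max() > 110:
            raise ValidationError("temperature range must lie within [0, 110] degC")


# --- CSV I/O ----------------------------------------------------------------


def read_series_csv(path: str | Path) -> TitrationSeries:
    """Read a titration series CSV with columns conc,intensity and metadata header.

    Metadata lines are ``# key: value`` comments above the header (residue,
    form, conc_unit)."""
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    residue = AtomRef.parse(meta.get("residue", "G22H1"))
    return TitrationSeries(
        residue=residue,
        form_tracked=meta.get("form", "na_form"),
        points=list(zip(df["conc"].astype(float), df["intensity"].astype(float))),
        conc_unit=meta.get("conc_unit", "mM"),
    )


def write_series_csv(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"# residue: {series.residue.token()}\n"
        f"# form: {series.form_tracked}\n"
        f"# conc_unit: {series.conc_unit}\n"
    )
    df = pd.DataFrame(series.points, columns=["conc", "intensity"])
    path.write_text(header + df.to_csv(index=False))


def read_trace_csv(path: str | Path) -> KineticTrace:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return KineticTrace(
        times=df["time"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        kind=meta.get("kind", "hdx"),
        time_unit=meta.get("time_unit", "min"),
        dead_time=float(meta.get("dead_time", 0.0)),
        label=meta.get("label", ""),
    )


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"# kind: {trace.kind}\n# time_unit: {trace.time_unit}\n"
        f"# dead_time: {trace.dead_time!r}\n# label: {trace.label}\n"
    )
    df = pd.DataFrame({"time": trace.times, "signal": trace.signal})
    path.write_text(header + df.to_csv(index=False))


def read_melting_csv(path: str | Path) -> MeltingCurve:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return MeltingCurve(
        temperature=df["temperature"].to_numpy(float),
        ellipticity=df["ellipticity"].to_numpy(float),
        wavelength_nm=float(meta.get("wavelength_nm", 295.0)),
    )


def write_melting_csv(curve: MeltingCurve, path: str | Path) -> None:
    path = Path(path)
    header = f"# wavelength_nm: {curve.wavelength_nm!r}\n"
    df = pd.DataFrame(
        {"temperature": curve.temperature, "ellipticity": curve.ellipticity}
    )
    path.write_text(header + df.to_csv(index=False))


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        if not raw.startswith("#"):
            break
        body = raw.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _one_site_profile_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit y = plateau + (y0 - plateau) / (1 + x/x50) by profiled least squares.

    For fixed x50 the model is linear in (plateau, amplitude); the 1-D
    search over log10(x50) is solved with a bounded scalar minimizer, which
    keeps the fit deterministic and affine-equivariant in y.  Returns
    (y0, plateau, x50).
    """
    xpos = x[x > 0]
    lo = np.log10(xpos.min()) - 2.0
    hi = np.log10(xpos.max()) + 2.0

    def solve(logx50: float) -> tuple[float, np.ndarray]:
        x50 = 10.0**logx50
        basis = 1.0 / (1.0 + x / x50)  # 1 at x=0 -> coefficient is (y0 - plateau)
        A = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return float(resid @ resid), coef

    res = minimize_scalar(lambda l: solve(l)[0], bounds=(lo, hi), method="bounded")
    rss, coef = solve(float(res.x))
    plateau, amp = float(coef[0]), float(coef[1])
    return plateau + amp, plateau, 10.0 ** float(res.x)


def normalize_series(
    raw: Sequence[tuple[float, float]],
    form_tracked: str = "na_form",
    residue: AtomRef | None = None,
    conc_unit: str = "mM",
) -> TitrationSeries:
    """Normalize raw imino intensities onto a fractional [0, 1] scale.

    For a disappearing (``na_form``) signal the zero-titrant intensity maps
    to 1 and the fitted end plateau to 0; for an appearing (``k_form``)
    signal the zero-titrant intensity maps to 0 and the fitted plateau to 1.
    The plateau anchor comes from a one-site binding fit rather than the
    last measured point, so an unfinished titration does not bias the scale.
    Normalization constants are recorded on the returned series.
    """
    pts = sorted(raw)
    if len(pts) < 2:
        raise ValidationError("need at least 2 points to normalize")
    x = np.array([c for c, _ in pts], dtype=float)
    y = np.array([i for _, i in pts], dtype=float)
    if x[0] != 0:
        raise ValidationError("a zero-titrant point is required for normalization")
    if np.allclose(y, y[0], rtol=0, atol=1e-12 * max(1.0, abs(y[0]))):
        raise DegenerateSeriesError("constant intensity series cannot be normalized")
    if not np.any(np.abs(y) > 0):
        raise DegenerateSeriesError("all-zero intensity series")

    if len(pts) == 2:
        y0, plateau = float(y[0]), float(y[-1])
        x50 = float("nan")
    else:
        y0_fit, plateau, x50 = _one_site_profile_fit(x, y)
        y0 = float(y[0])  # anchor the measured zero-titrant point exactly
    span = y0 - plateau
    if span == 0:
        raise DegenerateSeriesError("zero dynamic range after plateau fit")
    frac = (y - plateau) / span  # 1 at zero titrant, 0 at plateau
    if form_tracked == "k_form":
        frac = 1.0 - frac  # 0 at zero titrant, 1 at plateau
    if residue is None:
        residue = AtomRef(1, "H1")
    return TitrationSeries(
        residue=residue,
        form_tracked=form_tracked,
        points=list(zip(x.tolist(), frac.tolist())),
        conc_unit=conc_unit,
        normalization={"anchor_zero": y0, "plateau": plateau, "x50": x50},
    )
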