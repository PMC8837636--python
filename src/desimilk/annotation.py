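"""Lipid-marker annotation: elemental formulas, monoisotopic masses and
matching of observed ions against the bundled marker table.

All markers were measured in positive ion polarity as singly protonated
molecular ions, so the only adduct model implemented is [M+H]+ with the
electron-corrected proton mass (1.00727646 Da).  Atomic monoisotopic
masses are fixed constants so that computed masses are bit-reproducible;
they reproduce every accurate mass in the bundled table to 4 decimal
places.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ElementalFormula",
    "MarkerRecord",
    "MassMatch",
    "FormulaError",
    "MarkerTableError",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mass",
    "ppm_error",
    "load_marker_table",
    "verify_marker_table",
    "match_peak",
    "match_fragments",
]

#: Monoisotopic atomic masses (Da), most abundant isotope.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
}

#: Proton mass in Da (H atom minus one electron mass).
PROTON_MASS: float = 1.00727646

#: Hill-order for serialisation: C, H first, remaining symbols alphabetical.
_HILL_HEAD = ("C", "H")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

_MARKER_SHA256 = "aa5de7efa8e1f9814c563acd1d71f1d62a307364c3284f5d90b98085877b19fc"


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


class MarkerTableError(RuntimeError):
    """Raised when the bundled marker table fails its integrity check."""


@dataclass(frozen=True)
class ElementalFormula:
    """Multiset of atoms, e.g. ``{C: 27, H: 53, O: 8, P: 1}``.

    Only elements with a fixed monoisotopic mass constant are accepted;
    counts are strictly positive.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for elem, n in self.counts.items():
            if elem not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol {elem!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {elem} must be a positive integer, got {n!r}")

    def __str__(self) -> str:
        return serialize_formula(self)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalFormula(merged)


@dataclass(frozen=True)
class MarkerRecord:
    """One row of the bundled marker table.

    ``p1`` and ``pcorr`` are the S-plot covariance/correlation statistics
    under the cow = -1 encoding: cow-milk markers carry negative values,
    markers of the other species positive ones.
    """

    milk_type: str
    mass_bin: float
    p1: float
    pcorr: float
    representative_mass: float
    accurate_mass: float
    formula: ElementalFormula
    lipid_name: str
    lm_id: str


@dataclass(frozen=True)
class MassMatch:
    observed_mz: float
    marker: MarkerRecord
    error_ppm: float


def parse_formula(text: str) -> ElementalFormula:
    """Parse an elemental formula such as ``"C27H53O8P"``.

    The grammar is a concatenation of element symbols, each optionally
    followed by an integer count >= 2 (an absent count means one atom).
    No parentheses, isotopes or charges.
    """
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        pos = m.end()
        elem, digits = m.group(1), m.group(2)
        if elem not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {elem} in {text!r}")
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(text):
        raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
    return ElementalFormula(counts)


def serialize_formula(f: ElementalFormula) -> str:
    """Serialise in Hill order (C, H, then alphabetical); count 1 omitted."""
    order = [e for e in _HILL_HEAD if e in f.counts]
    order += sorted(e for e in f.counts if e not in _HILL_HEAD)
    return "".join(f"{e}{f.counts[e] if f.counts[e] > 1 else ''}" for e in order)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return sum(ATOMIC_MASS[e] * n for e, n in f.counts.items())


def protonated_mass(f: ElementalFormula) -> float:
    """m/z of the singly protonated ion [M+H]+."""
    return monoisotopic_mass(f) + PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def _marker_table_path() -> Path:
    return Path(str(resources.files("desimilk").joinpath("data/marker_table.csv")))


def load_marker_table(path: str | Path | None = None, *, verify_checksum: bool = True) -> list[MarkerRecord]:
    """Load the bundled marker table (28 records; 23 cow, 5 other species).

    The bundled file is checksummed; pass ``path`` to load a user table
    (checksum verification is then skipped).
    """
    bundled = path is None
    p = _marker_table_path() if bundled else Path(path)
    raw = p.read_bytes()
    if bundled and verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _MARKER_SHA256:
            raise MarkerTableError(
                f"bundled marker table corrupted: sha256 {digest} != {_MARKER_SHA256}"
            )
    lines = raw.decode("utf-8").strip().splitlines()
    header = lines[0].split(",")
    expected = ["milk_type", "mass_bin", "p1", "pcorr", "representative_mass",
                "accurate_mass", "formula", "lipid_name", "lm_id"]
    if header != expected:
        raise MarkerTableError(f"marker table header {header} != {expected}")
    records = []
    for ln in lines[1:]:
        c = ln.split(",")
        if len(c) != 9:
            raise MarkerTableError(f"malformed marker row: {ln!r}")
        records.append(MarkerRecord(
            milk_type=c[0],
            mass_bin=float(c[1]),
            p1=float(c[2]),
            pcorr=float(c[3]),
            representative_mass=float(c[4]),
            accurate_mass=float(c[5]),
            formula=parse_formula(c[6]),
            lipid_name=c[7],
            lm_id=c[8],
        ))
    return records


@dataclass
class MarkerVerification:
    """Per-record recomputation of [M+H]+ against the printed accurate mass."""

    tol: float
    deviations: dict[str, float] = field(default_factory=dict)  # lipid_name -> Da
    passed: dict[str, bool] = field(default_factory=dict)
    bin_anomalies: list[str] = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return sum(self.passed.values())

    @property
    def all_pass(self) -> bool:
        return all(self.passed.values())


def verify_marker_table(tol: float = 0.001, table: list[MarkerRecord] | None = None) -> MarkerVerification:
    """Recompute every marker's [M+H]+ and compare to its accurate mass.

    Also flags records whose representative mass does not fall inside the
    printed 0.2 Da mass bin (one such anomaly ships in the bundled table:
    the M(IP)2C(36:0;O3) row is labelled 1232.7 while its representative
    mass 1230.6704 bins at 1230.7; it is shipped as printed).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if table is None:
        table = load_marker_table()
    report = MarkerVerification(tol=tol)
    for rec in table:
        dev = protonated_mass(rec.formula) - rec.accurate_mass
        report.deviations[rec.lipid_name] = dev
        report.passed[rec.lipid_name] = abs(dev) <= tol
        # half-open 0.2 Da bins centred on odd multiples of 0.1
        lab = 100.0 + int((rec.representative_mass - 100.0) / 0.2) * 0.2 + 0.1
        if abs(lab - rec.mass_bin) > 1e-6:
            report.bin_anomalies.append(rec.lipid_name)
    return report


def match_peak(observed: float, table: list[MarkerRecord], tol_ppm: float) -> list[MassMatch]:
    """All markers whose accurate mass lies within ``tol_ppm`` of the peak,
    sorted by absolute ppm error."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out = []
    for rec in table:
        err = ppm_error(observed, rec.accurate_mass)
        if abs(err) <= tol_ppm:
            out.append(MassMatch(observed_mz=observed, marker=rec, error_ppm=err))
    out.sort(key=lambda m: abs(m.error_ppm))
    return out


def match_fragments(
    fragment_mzs: list[float], table: list[MarkerRecord], tol: float
) -> list[tuple[float, MassMatch]]:
    """Bin-resolution matching of MS/MS fragment masses against markers.

    A fragment matches a marker when it falls within ``tol`` Da of either
    the marker's accurate mass or its mass-bin label; ppm error is
    reported against the accurate mass.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    out: list[tuple[float, MassMatch]] = []
    for frag in fragment_mzs:
        for rec in table:
            d_acc = abs(frag - rec.accurate_mass)
            d_bin = abs(frag - rec.mass_bin)
            if min(d_acc, d_bin) <= tol:
                out.append((frag, MassMatch(
                    observed_mz=frag,
                    marker=rec,
                    error_ppm=ppm_error(frag, rec.accurate_mass),
                )))
    return out
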