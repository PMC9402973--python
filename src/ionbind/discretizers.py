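"""Discretization of per-residue annotations onto categorical alphabets.

Every per-residue track (amino acid, secondary structure, relative solvent
accessibility, phi/psi dihedrals, predicted disorder, side-chain charge,
hydropathy) is mapped onto a small ordered alphabet whose *last* symbol is a
dedicated vacancy category reserved for the pseudo-residues used to pad
chain ends.  The interval boundaries follow right-closed interval
conventions throughout: a value equal to a boundary belongs to the interval
it closes on the right.

Category counts (including the vacancy symbol):

====================  ===
amino acid             21
secondary structure     4
solvent accessibility   5
phi angle               3
psi angle               4
disorder                3
charge                  4
hydropathy              7
====================  ===
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotations import AnnotatedChain, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VACANCY_SYMBOL = "-"

#: fixed track order used for discretized chains and fragments
TRACKS = ("aa", "ss", "rsa", "phi", "psi", "disorder", "charge", "hydropathy")

#: the six tracks that feed the component / conservation encoders
CONSERVATION_TRACKS = ("aa", "ss", "rsa", "phi", "psi", "disorder")


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered categorical alphabet with a single vacancy category."""

    name: str
    categories: tuple[str, ...]  # vacancy last

    @property
    def q(self) -> int:
        """Number of categories, vacancy included."""
        return len(self.categories)

    @property
    def vacancy(self) -> int:
        return self.q - 1


SCHEMES: dict[str, CategoryScheme] = {
    "aa": CategoryScheme("aa", tuple(AMINO_ACIDS) + (VACANCY_SYMBOL,)),
    "ss": CategoryScheme("ss", ("H", "E", "C", VACANCY_SYMBOL)),
    "rsa": CategoryScheme("rsa", ("I", "II", "III", "IV", VACANCY_SYMBOL)),
    "phi": CategoryScheme("phi", ("I", "II", VACANCY_SYMBOL)),
    "psi": CategoryScheme("psi", ("I", "II", "III", VACANCY_SYMBOL)),
    "disorder": CategoryScheme("disorder", ("I", "II", VACANCY_SYMBOL)),
    "charge": CategoryScheme(
        "charge", ("positive", "negative", "neutral", VACANCY_SYMBOL)
    ),
    "hydropathy": CategoryScheme(
        "hydropathy",
        (
            "strong_hydrophilic",
            "strong_hydrophobic",
            "weak_amphipathic",
            "proline",
            "glycine",
            "cysteine",
            VACANCY_SYMBOL,
        ),
    ),
}

#: per-track q (vacancy included), in TRACKS order
TRACK_Q = {name: SCHEMES[name].q for name in TRACKS}

_SS_INDEX = {"H": 0, "E": 1, "C": 2}
_RSA_BOUNDS = np.array([0.2, 0.45, 0.6])
_PSI_BOUNDS = np.array([15.0, 135.0])


@dataclass(frozen=True)
class ResidueClasses:
    """Charge and hydropathy class membership for the 20 amino acids."""

    charge: Mapping[str, str]
    hydropathy: Mapping[str, str]
    charge_index: Mapping[str, int] = field(init=False)
    hydropathy_index: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for table, scheme in ((self.charge, "charge"), (self.hydropathy, "hydropathy")):
            missing = set(AMINO_ACIDS) - set(table)
            extra = set(table) - set(AMINO_ACIDS)
            if missing or extra:
                raise ValueError(
                    f"{scheme} table must cover the 20 canonical amino acids "
                    f"exactly once (missing {sorted(missing)}, extra {sorted(extra)})"
                )
            classes = set(table.values())
            allowed = set(SCHEMES[scheme].categories[:-1])
            if not classes <= allowed:
                raise ValueError(
                    f"unknown {scheme} classes {sorted(classes - allowed)}; "
                    f"allowed: {sorted(allowed)}"
                )
        cats = SCHEMES["charge"].categories
        object.__setattr__(
            self, "charge_index", {aa: cats.index(c) for aa, c in self.charge.items()}
        )
        cats = SCHEMES["hydropathy"].categories
        object.__setattr__(
            self,
            "hydropathy_index",
            {aa: cats.index(c) for aa, c in self.hydropathy.items()},
        )


def load_residue_classes(path=None) -> ResidueClasses:
    """Load charge/hydropathy tables from YAML (package default if no path)."""
    if path is None:
        text = (
            resources.files("ionbind").joinpath("data/residue_classes.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tables = {}
    for scheme in ("charge", "hydropathy"):
        table: dict[str, str] = {}
        for cls, members in raw[scheme].items():
            for aa in members:
                if aa in table:
                    raise ValueError(f"{scheme}: amino acid {aa} listed twice")
                table[aa] = cls
        tables[scheme] = table
    return ResidueClasses(charge=tables["charge"], hydropathy=tables["hydropathy"])


DEFAULT_CLASSES = load_residue_classes()


# ---------------------------------------------------------------------------
# scalar discretizers (codes are 0-based indices into the scheme's categories)


def discretize_disorder(x: float) -> int:
    """Two-state disorder code: 0 (ordered) for x in [0, 0.5], 1 for (0.5, 1]."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"disorder value {x!r} outside [0, 1]")
    return int(x > 0.5)


def discretize_rsa(x: float) -> int:
    """Four-interval solvent-accessibility code.

    Intervals are (0,0.2], (0.2,0.45], (0.45,0.6], (0.6,0.85]; values at 0
    fall in the first interval and values above 0.85 clamp to the last, so
    the map is total on [0, 1].
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"RSA value {x!r} outside [0, 1]")
    return int(np.searchsorted(_RSA_BOUNDS, x, side="left"))


def discretize_phi(x: float) -> int:
    """Two-interval phi code: 0 for [-180, -75], 1 for (-75, 180]."""
    if not -180.0 <= x <= 180.0:
        raise ValueError(f"phi angle {x!r} outside [-180, 180]")
    return int(x > -75.0)


def discretize_psi(x: float) -> int:
    """Three-interval psi code: [-180,15] -> 0, (15,135] -> 1, (135,180] -> 2."""
    if not -180.0 <= x <= 180.0:
        raise ValueError(f"psi angle {x!r} outside [-180, 180]")
    return int(np.searchsorted(_PSI_BOUNDS, x, side="left"))


def discretize_ss(s: str) -> int:
    if s not in _SS_INDEX:
        raise ValueError(f"unknown secondary-structure code {s!r} (expected H/E/C)")
    return _SS_INDEX[s]


def classify_charge(aa: str, classes: ResidueClasses = DEFAULT_CLASSES) -> int:
    """Charge class index of a canonical amino acid (0=positive, 1=negative, 2=neutral)."""
    try:
        return classes.charge_index[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def classify_hydropathy(aa: str, classes: ResidueClasses = DEFAULT_CLASSES) -> int:
    """Hydropathy class index of a canonical amino acid under the 6-way scheme."""
    try:
        return classes.hydropathy_index[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def classify_aa(aa: str) -> int:
    idx = AMINO_ACIDS.find(aa)
    if idx < 0:
        if aa == VACANCY_SYMBOL:
            return SCHEMES["aa"].vacancy
        raise ValueError(f"unknown amino acid {aa!r}")
    return idx


# ---------------------------------------------------------------------------
# chain-level discretization


@dataclass
class DiscretizedChain:
    """Per-residue category codes for all eight tracks of one chain.

    ``codes`` has shape (n_residues, 8) in :data:`TRACKS` order; vacancy
    codes never appear for real residues.
    """

    chain_id: str
    codes: np.ndarray  # (n, 8) int16
    labels: np.ndarray  # (n,) uint8

    def __len__(self) -> int:
        return self.codes.shape[0]


def discretize_chain(
    chain: AnnotatedChain, classes: ResidueClasses = DEFAULT_CLASSES
) -> DiscretizedChain:
    """Vectorized discretization of a whole annotated chain.

    Residues remapped to the vacancy symbol upstream get the vacancy code in
    the aa/charge/hydropathy tracks; real annotations are validated against
    their domains and errors carry 1-based position context.
    """
    n = len(chain.sequence)
    codes = np.empty((n, len(TRACKS)), dtype=np.int16)

    aa_codes = np.empty(n, dtype=np.int16)
    charge_codes = np.empty(n, dtype=np.int16)
    hydro_codes = np.empty(n, dtype=np.int16)
    for i, aa in enumerate(chain.sequence):
        try:
            aa_codes[i] = classify_aa(aa)
            if aa == VACANCY_SYMBOL:
                charge_codes[i] = SCHEMES["charge"].vacancy
                hydro_codes[i] = SCHEMES["hydropathy"].vacancy
            else:
                charge_codes[i] = classify_charge(aa, classes)
                hydro_codes[i] = classify_hydropathy(aa, classes)
        except ValueError as exc:
            raise ValidationError(
                f"chain {chain.chain_id} position {i + 1}: {exc}"
            ) from exc

    ss_codes = np.empty(n, dtype=np.int16)
    for i, s in enumerate(chain.ss):
        try:
            ss_codes[i] = discretize_ss(s)
        except ValueError as exc:
            raise ValidationError(
                f"chain {chain.chain_id} position {i + 1}: {exc}"
            ) from exc

    rsa = np.asarray(chain.rsa, dtype=float)
    phi = np.asarray(chain.phi, dtype=float)
    psi = np.asarray(chain.psi, dtype=float)
    dis = np.asarray(chain.disorder, dtype=float)
    for name, arr, lo, hi in (
        ("rsa", rsa, 0.0, 1.0),
        ("phi", phi, -180.0, 180.0),
        ("psi", psi, -180.0, 180.0),
        ("disorder", dis, 0.0, 1.0),
    ):
        bad = np.nonzero((arr < lo) | (arr > hi) | ~np.isfinite(arr))[0]
        if bad.size:
            raise ValidationError(
                f"chain {chain.chain_id} position {bad[0] + 1}: "
                f"{name} value {arr[bad[0]]!r} outside [{lo}, {hi}]"
            )

    codes[:, 0] = aa_codes
    codes[:, 1] = ss_codes
    codes[:, 2] = np.searchsorted(_RSA_BOUNDS, rsa, side="left")
    codes[:, 3] = (phi > -75.0).astype(np.int16)
    codes[:, 4] = np.searchsorted(_PSI_BOUNDS, psi, side="left")
    codes[:, 5] = (dis > 0.5).astype(np.int16)
    codes[:, 6] = charge_codes
    codes[:, 7] = hydro_codes
    return DiscretizedChain(
        chain_id=chain.chain_id,
        codes=codes,
        labels=np.asarray(chain.labels, dtype=np.uint8),
    )


def vacancy_row() -> np.ndarray:
    """The category-code row a pseudo-residue occupies in every track."""
    return np.array([SCHEMES[t].vacancy for t in TRACKS], dtype=np.int16)
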