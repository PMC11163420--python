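"""Idealized spin arrays and beta-sheet lattice models.

The coordinate frame is Cartesian Angstrom, right-handed:

* x — strand axis (peptide backbone direction),
* y — hydrogen-bond axis (inter-strand direction within a sheet),
* z — stacking axis (sheet-to-sheet direction).

Strands are idealized as points on a line with one point per residue
(``residue_rise`` apart); backbone and side-chain label sites are
pseudo-atoms placed at fixed offsets from the residue point.  Antiparallel
neighbors are generated by a two-fold rotation of the local strand
coordinates (x -> span - x, y-offsets negated), which reverses the strand
direction; antiparallel sheet stacking additionally flips the z offsets.
Side chains are not modeled atomistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import ISOTOPES

__all__ = [
    "CSAParameters",
    "SpinSite",
    "SpinSystem",
    "SheetModel",
    "Contact",
    "build_linear_spin_array",
    "build_sheet_model",
    "extract_spin_system",
    "predict_contacts",
    "write_model_pdb",
    "Q11_SEQUENCE",
    "SALT_BRIDGE_LABELS",
    "DEFAULT_BACKBONE_OFFSETS",
]

#: the Q11 self-assembling peptide, Ac-QQKFQFQFEQQ-Am
Q11_SEQUENCE = "QQKFQFQFEQQ"

#: pseudo-atom offsets (A) from the residue point, in local strand coordinates
DEFAULT_BACKBONE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "N": (-1.2, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "CO": (1.2, 0.0, 0.0),
}

#: side-chain pseudo-atoms reproducing the idealized 4 A K3 Nz - E9 Cd
#: salt-bridge contact between antiparallel neighbor strands at 5 A spacing
SALT_BRIDGE_LABELS: dict[str, tuple[float, float, float]] = {
    "K3 NZ": (0.0, 0.5, 0.0),
    "E9 CD": (0.0, 0.5, 0.0),
}

_ELEMENT_ISOTOPE = {"C": "C13", "N": "N15"}


class InvalidLabelError(ValueError):
    """A label references an unknown residue or atom."""


class EmptySelectionError(ValueError):
    """A site selection matched nothing."""


@dataclass(frozen=True)
class CSAParameters:
    """Chemical-shift-anisotropy tensor in Haeberlen convention.

    ``aniso_ppm`` is delta_zz - delta_iso; ``asymmetry`` (eta) is
    (delta_yy - delta_xx) / aniso.  The Euler angles (degrees, z-y-z)
    rotate the principal-axis system into the molecular frame; the
    all-zero default aligns the PAS with the molecular axes, i.e. the
    unique axis along the strand/array direction.
    """

    aniso_ppm: float
    asymmetry: float = 0.0
    alpha_deg: float = 0.0
    beta_deg: float = 0.0
    gamma_deg: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError(f"asymmetry must be in [0, 1], got {self.asymmetry}")

    def principal_values(self) -> tuple[float, float, float]:
        """Traceless principal values (xx, yy, zz) in ppm."""
        d = self.aniso_ppm
        return (
            -0.5 * d * (1.0 + self.asymmetry),
            -0.5 * d * (1.0 - self.asymmetry),
            d,
        )


@dataclass(frozen=True)
class SpinSite:
    site_id: str
    isotope: str
    position: np.ndarray  #: (3,) in Angstrom
    csa: CSAParameters | None = None
    residue_label: str | None = None

    def __post_init__(self):
        if self.isotope not in ISOTOPES:
            raise ValueError(f"unsupported isotope {self.isotope!r}")
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("site position must be finite")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class SpinSystem:
    """An ordered collection of labeled spin-1/2 sites."""

    sites: tuple[SpinSite, ...]
    name: str = ""

    def __post_init__(self):
        sites = tuple(self.sites)
        if len(sites) < 1:
            raise ValueError("a spin system needs at least one site")
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")
        pos = np.array([s.position for s in sites])
        if len(sites) > 1:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0.5:
                raise ValueError("all pairwise distances must exceed 0.5 A")
        object.__setattr__(self, "sites", sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def isotopes(self) -> tuple[str, ...]:
        return tuple(s.isotope for s in self.sites)

    def distance(self, id_a: str, id_b: str) -> float:
        lookup = {s.site_id: s for s in self.sites}
        return float(np.linalg.norm(lookup[id_a].position - lookup[id_b].position))

    def distance_matrix(self) -> np.ndarray:
        p = self.positions
        return np.linalg.norm(p[:, None] - p[None, :], axis=-1)

    def select(self, site_ids: Sequence[str], name: str = "") -> "SpinSystem":
        lookup = {s.site_id: s for s in self.sites}
        missing = [i for i in site_ids if i not in lookup]
        if missing:
            raise KeyError(f"unknown site_ids: {missing}")
        return SpinSystem(tuple(lookup[i] for i in site_ids), name or self.name)

    def to_dict(self) -> dict:
        out = {"name": self.name, "sites": []}
        for s in self.sites:
            rec = {
                "site_id": s.site_id,
                "isotope": s.isotope,
                "xyz": [float(v) for v in s.position],
            }
            if s.residue_label:
                rec["residue_label"] = s.residue_label
            if s.csa is not None:
                rec["csa"] = {
                    "aniso_ppm": s.csa.aniso_ppm,
                    "asymmetry": s.csa.asymmetry,
                    "alpha_deg": s.csa.alpha_deg,
                    "beta_deg": s.csa.beta_deg,
                    "gamma_deg": s.csa.gamma_deg,
                }
            out["sites"].append(rec)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "SpinSystem":
        sites = []
        for rec in data["sites"]:
            csa = CSAParameters(**rec["csa"]) if rec.get("csa") else None
            sites.append(
                SpinSite(
                    site_id=rec["site_id"],
                    isotope=rec["isotope"],
                    position=np.asarray(rec["xyz"], dtype=float),
                    csa=csa,
                    residue_label=rec.get("residue_label"),
                )
            )
        return cls(tuple(sites), data.get("name", ""))


def build_linear_spin_array(
    n_spins: int,
    spacing: float,
    isotope_pattern: Sequence[str],
    csa: CSAParameters | None = None,
    name: str = "",
) -> SpinSystem:
    """Collinear, equally spaced spin array along the x axis.

    ``isotope_pattern`` is cycled over the sites, e.g. ``["C13", "N15"]``
    produces an alternating heteronuclear array.  ``csa``, when given, is
    attached to every 13C site.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    pattern = list(isotope_pattern)
    if not pattern:
        raise ValueError("isotope_pattern must be non-empty")
    sites = []
    for i in range(n_spins):
        iso = pattern[i % len(pattern)]
        sites.append(
            SpinSite(
                site_id=f"s{i}",
                isotope=iso,
                position=np.array([i * spacing, 0.0, 0.0]),
                csa=csa if iso == "C13" else None,
            )
        )
    label = name or f"linear_{n_spins}spin_{spacing:g}A"
    return SpinSystem(tuple(sites), label)


@dataclass(frozen=True)
class _Atom:
    """One pseudo-atom of a lattice model."""

    site_id: str
    residue: str  # e.g. "F4"
    atom: str  # e.g. "CO"
    sheet: int
    strand: int
    position: np.ndarray


@dataclass(frozen=True)
class SheetModel:
    """Idealized lattice of beta-strands.

    ``strand_arrangement`` fixes the relative direction of adjacent strands
    within a sheet, ``stacking`` the relative orientation of adjacent
    sheets.  ``label_sites`` adds side-chain pseudo-atoms, mapping labels
    like ``"K3 NZ"`` to offset vectors in local strand coordinates.
    ``registry_shift`` translates every reversed strand by that many
    residues along x (the registry of antiparallel models is not fixed by
    the idealized geometry and is exposed as a parameter).
    """

    strand_arrangement: str = "parallel"
    stacking: str = "none"
    n_strands_per_sheet: int = 10
    n_sheets: int = 1
    strand_spacing: float = 5.0
    sheet_spacing: float = 10.0
    residue_rise: float = 3.5
    sequence: str = Q11_SEQUENCE
    label_sites: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    registry_shift: int = 0

    def __post_init__(self):
        if self.strand_arrangement not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown arrangement {self.strand_arrangement!r}")
        if self.stacking not in ("parallel", "antiparallel", "none"):
            raise ValueError(f"unknown stacking {self.stacking!r}")
        if self.n_strands_per_sheet < 1 or self.n_sheets < 1:
            raise ValueError("strand and sheet counts must be positive")
        if min(self.strand_spacing, self.sheet_spacing, self.residue_rise) <= 0:
            raise ValueError("spacings must be positive")
        if self.n_sheets > 1 and self.stacking == "none":
            object.__setattr__(self, "stacking", "parallel")
        for label in self.label_sites:
            self._parse_label(label)

    # -- label handling ------------------------------------------------
    def _parse_label(self, label: str) -> tuple[int, str]:
        """``"F4 CO"`` -> (residue index 0-based, atom name)."""
        try:
            res, atom = label.split()
            letter, idx = res[0], int(res[1:])
        except (ValueError, IndexError):
            raise InvalidLabelError(f"malformed label {label!r}") from None
        if not 1 <= idx <= len(self.sequence):
            raise InvalidLabelError(f"residue index out of range in {label!r}")
        if self.sequence[idx - 1] != letter:
            raise InvalidLabelError(
                f"label {label!r} does not match sequence residue "
                f"{self.sequence[idx - 1]}{idx}"
            )
        if atom not in DEFAULT_BACKBONE_OFFSETS and label not in self.label_sites:
            raise InvalidLabelError(f"unknown atom in label {label!r}")
        return idx - 1, atom

    @property
    def strand_span(self) -> float:
        return (len(self.sequence) - 1) * self.residue_rise

    def strand_reversed(self, sheet: int, strand: int) -> bool:
        rev = False
        if self.strand_arrangement == "antiparallel" and strand % 2 == 1:
            rev = not rev
        if self.stacking == "antiparallel" and sheet % 2 == 1:
            rev = not rev
        return rev

    def strand_direction(self, sheet: int, strand: int) -> np.ndarray:
        """Unit N->C direction vector of a strand."""
        return np.array([-1.0 if self.strand_reversed(sheet, strand) else 1.0, 0.0, 0.0])

    def atoms(self) -> list[_Atom]:
        """All pseudo-atoms of the lattice (backbone + label sites)."""
        offsets: dict[tuple[int, str], np.ndarray] = {}
        for i in range(len(self.sequence)):
            for atom, off in DEFAULT_BACKBONE_OFFSETS.items():
                offsets[(i, atom)] = np.asarray(off, dtype=float)
        for label, off in self.label_sites.items():
            i, atom = self._parse_label(label)
            offsets[(i, atom)] = np.asarray(off, dtype=float)

        span = self.strand_span
        out = []
        for m in range(self.n_sheets):
            sheet_flip = self.stacking == "antiparallel" and m % 2 == 1
            for s in range(self.n_strands_per_sheet):
                arr_flip = self.strand_arrangement == "antiparallel" and s % 2 == 1
                for (i, atom), off in offsets.items():
                    local = np.array([i * self.residue_rise, 0.0, 0.0]) + off
                    # in-sheet reversal: two-fold rotation about z
                    if arr_flip:
                        local = np.array([span - local[0], -local[1], local[2]])
                    # sheet reversal: two-fold rotation about y (flips face)
                    if sheet_flip:
                        local = np.array([span - local[0], local[1], -local[2]])
                    if arr_flip or sheet_flip:
                        local[0] += self.registry_shift * self.residue_rise
                    pos = local + np.array(
                        [0.0, s * self.strand_spacing, m * self.sheet_spacing]
                    )
                    res = f"{self.sequence[i]}{i + 1}"
                    out.append(
                        _Atom(
                            site_id=f"m{m}.s{s}.{res}.{atom}",
                            residue=res,
                            atom=atom,
                            sheet=m,
                            strand=s,
                            position=pos,
                        )
                    )
        return out

    def label_atoms(self, labels: Iterable[str]) -> list[_Atom]:
        wanted = set()
        for label in labels:
            i, atom = self._parse_label(label)
            wanted.add((f"{self.sequence[i]}{i + 1}", atom))
        return [a for a in self.atoms() if (a.residue, a.atom) in wanted]


def build_sheet_model(
    arrangement: str = "parallel",
    stacking: str = "none",
    n_strands: int = 10,
    n_sheets: int = 1,
    strand_spacing: float = 5.0,
    sheet_spacing: float = 10.0,
    labels: Mapping[str, tuple[float, float, float]] | None = None,
    sequence: str = Q11_SEQUENCE,
    residue_rise: float = 3.5,
    registry_shift: int = 0,
) -> SheetModel:
    """Construct an idealized beta-sheet lattice model.

    Defaults follow the idealized nanofiber geometry: 5 A strand spacing,
    3.5 A residue rise, 10 A sheet spacing, Q11 sequence.
    """
    return SheetModel(
        strand_arrangement=arrangement,
        stacking=stacking,
        n_strands_per_sheet=n_strands,
        n_sheets=n_sheets,
        strand_spacing=strand_spacing,
        sheet_spacing=sheet_spacing,
        residue_rise=residue_rise,
        sequence=sequence,
        label_sites=dict(labels or {}),
        registry_shift=registry_shift,
    )


def _isotope_for_atom(atom: str) -> str:
    element = atom[0]
    if element not in _ELEMENT_ISOTOPE:
        raise InvalidLabelError(f"cannot infer isotope for atom {atom!r}")
    return _ELEMENT_ISOTOPE[element]


def extract_spin_system(
    model: SheetModel,
    selection: Iterable[str],
    max_spins: int = 8,
    csa: CSAParameters | None = None,
    name: str = "",
) -> SpinSystem:
    """Extract the ``max_spins`` selected label sites nearest the centroid.

    ``selection`` lists labels like ``"F4 CO"``; isotopes are inferred from
    the atom element (C -> 13C, N -> 15N).  Ordering is deterministic:
    by distance to the centroid of the selected sites, then by site_id.
    """
    if max_spins < 1:
        raise ValueError("max_spins must be >= 1")
    atoms = model.label_atoms(selection)
    if not atoms:
        raise EmptySelectionError("selection matched no lattice sites")
    pos = np.array([a.position for a in atoms])
    centroid = pos.mean(axis=0)
    dist = np.linalg.norm(pos - centroid, axis=1)
    order = sorted(range(len(atoms)), key=lambda i: (round(dist[i], 9), atoms[i].site_id))
    chosen = [atoms[i] for i in order[:max_spins]]
    sites = []
    for a in chosen:
        iso = _isotope_for_atom(a.atom)
        sites.append(
            SpinSite(
                site_id=a.site_id,
                isotope=iso,
                position=a.position,
                csa=csa if iso == "C13" else None,
                residue_label=f"{a.residue} {a.atom}",
            )
        )
    return SpinSystem(tuple(sites), name or f"{model.strand_arrangement}_selection")


@dataclass(frozen=True)
class Contact:
    """A detectable residue-residue proximity."""

    residue_a: str
    residue_b: str
    min_distance: float
    kind: str  # "intra_strand" | "inter_strand" | "inter_sheet"

    @property
    def pair(self) -> frozenset:
        return frozenset((self.residue_a, self.residue_b))


def predict_contacts(
    model: SheetModel,
    labeled_residues: Iterable[str],
    cutoff: float = 6.0,
) -> set[Contact]:
    """Residue pairs with any inter-label atom distance within ``cutoff`` (A).

    The 6 A default is the distance range over which 13C-13C correlation
    (DARR) crosspeaks are detectable.  Pairs of the *same* residue name are
    excluded; each reported contact is annotated by the relation of the
    closest atom pair (same strand, same sheet, or across sheets).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = sorted(set(labeled_residues))
    if not residues:
        return set()
    # atoms to consider: backbone plus any configured side-chain labels
    atoms = [a for a in model.atoms() if a.residue in residues]
    best: dict[tuple[str, str], tuple[float, str]] = {}
    pos = np.array([a.position for a in atoms])
    for i, a in enumerate(atoms):
        d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
        for j_off in np.nonzero(d <= cutoff)[0]:
            b = atoms[i + 1 + j_off]
            if a.residue == b.residue:
                continue
            key = tuple(sorted((a.residue, b.residue)))
            if a.sheet != b.sheet:
                kind = "inter_sheet"
            elif a.strand != b.strand:
                kind = "inter_strand"
            else:
                kind = "intra_strand"
            dij = float(d[j_off])
            if key not in best or dij < best[key][0]:
                best[key] = (dij, kind)
    return {
        Contact(key[0], key[1], dist, kind) for key, (dist, kind) in best.items()
    }


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_model_pdb(model: SheetModel, destination) -> None:
    """Write the lattice as a PDB file, one chain per strand.

    Pseudo-atoms are written as standard ATOM records with the element
    inferred from the atom name; coordinates round-trip within 1e-3 A.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = model.atoms()
    n = len(atoms)
    arr = struc.AtomArray(n)
    for idx, a in enumerate(atoms):
        chain_index = a.sheet * model.n_strands_per_sheet + a.strand
        if chain_index >= len(_CHAIN_IDS):
            raise ValueError("too many strands for single-character PDB chain ids")
        arr.chain_id[idx] = _CHAIN_IDS[chain_index]
        arr.res_id[idx] = int(a.residue[1:])
        arr.res_name[idx] = _AA3.get(a.residue[0], "UNK")
        arr.atom_name[idx] = a.atom
        arr.element[idx] = a.atom[0]
        arr.coord[idx] = a.position
        arr.hetero[idx] = False
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(destination)
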