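"""Reading, writing and curating macromolecular structure files.

Thin typed layer over gemmi: multi-model PDB/mmCIF in, a list of
:class:`StructureModel` out.  Residues are classified into the kinds the
screening filters act on (DNA/RNA/modified nucleotide, amino acid,
other), alternate locations are reduced to the highest-occupancy
conformer, and hydrogens are dropped -- downstream geometry works on
heavy atoms of a single conformer.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._standard_bases import PURINE_RING, PYRIMIDINE_RING, STANDARD_BASE_COORDS

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureEnsemble",
    "classify_residue",
    "read_structure",
    "write_structure",
    "truncate_sidechain",
    "base_letter",
]

STANDARD_DNA_NAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
LEGACY_BASE_NAMES = {"A": "A", "C": "C", "G": "G", "T": "T",
                     "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T"}
STANDARD_RNA_NAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU", "URA", "URI"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray
    altloc: str | None = None
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ResidueRecord:
    chain_id: str
    number: int
    name: str
    atoms: list[AtomRecord]
    insertion_code: str = ""
    kind: str = "other"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


@dataclass
class StructureModel:
    model_index: int
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)

    def iter_residues(self):
        for residues in self.chains.values():
            yield from residues

    def find_residue(self, chain_id: str, number: int, insertion_code: str = "") -> ResidueRecord | None:
        for r in self.chains.get(chain_id, ()):
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def residue_position(self, residue: ResidueRecord) -> int:
        """Index of a residue within its chain's ordered list."""
        chain = self.chains[residue.chain_id]
        for i, r in enumerate(chain):
            if r is residue or (r.number == residue.number and r.insertion_code == residue.insertion_code):
                return i
        raise KeyError(f"residue {residue.id} not in model")


@dataclass
class StructureEnsemble:
    models: list[StructureModel]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.models)


def _has_base_ring(names: set[str]) -> bool:
    """True when enough ring atoms are present to call the residue base-like."""
    return (len(names.intersection(PURINE_RING)) >= 6
            or len(names.intersection(PYRIMIDINE_RING)) >= 5)


def classify_residue(residue: ResidueRecord) -> str:
    """Classify a residue as dna_nucleotide / rna_nucleotide /
    modified_nucleotide / amino_acid / other.

    The rules mirror the screening filters: standard deoxynucleotide
    names (or legacy one-letter names lacking a ribose O2') are DNA; an
    O2' or a standard RNA name marks RNA; base-like rings under a
    nonstandard name mark a modified nucleotide.  Total -- anything
    unrecognized falls through to ``other``.
    """
    names = residue.atom_names()
    rname = residue.name.strip().upper()
    has_o2prime = "O2'" in names or "O2*" in names
    if rname in STANDARD_DNA_NAMES and not has_o2prime:
        return "dna_nucleotide"
    if rname in LEGACY_BASE_NAMES and not has_o2prime and _has_base_ring(names):
        return "dna_nucleotide"
    if has_o2prime and (_has_base_ring(names) or rname in STANDARD_RNA_NAMES
                        or rname in STANDARD_DNA_NAMES):
        return "rna_nucleotide"
    if rname in STANDARD_RNA_NAMES and rname not in LEGACY_BASE_NAMES:
        return "rna_nucleotide"
    if rname in AMINO_ACIDS:
        return "amino_acid"
    if _has_base_ring(names):
        return "modified_nucleotide"
    return "other"


def base_letter(residue: ResidueRecord) -> str | None:
    """One-letter base code (A/C/G/T) of a DNA nucleotide, else None."""
    rname = residue.name.strip().upper()
    if rname in STANDARD_DNA_NAMES:
        return STANDARD_DNA_NAMES[rname]
    if rname in LEGACY_BASE_NAMES:
        return LEGACY_BASE_NAMES[rname]
    return None


def _classify_all(model: StructureModel) -> None:
    for res in model.iter_residues():
        res.kind = classify_residue(res)


def _convert_gemmi_model(gmodel: gemmi.Model, index: int) -> StructureModel:
    model = StructureModel(model_index=index)
    for gchain in gmodel:
        residues: list[ResidueRecord] = []
        for gres in gchain:
            # collapse altlocs: keep highest occupancy per atom name
            chosen: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.element.name in ("H", "D"):
                    continue
                prev = chosen.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    chosen[ga.name] = ga
            atoms = [
                AtomRecord(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    altloc=(ga.altloc if ga.altloc != "\x00" and ga.altloc else None),
                    occupancy=ga.occ,
                )
                for ga in chosen.values()
            ]
            if not atoms:
                continue
            residues.append(
                ResidueRecord(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: (r.number, r.insertion_code))
        if residues:
            model.chains[gchain.name] = residues
    _classify_all(model)
    return model


def read_structure(path, format_hint: str = "auto",
                   trajectory: bool = False) -> StructureEnsemble:
    """Read a PDB or mmCIF file into a :class:`StructureEnsemble`.

    One StructureModel per MODEL record / model block.  With
    ``trajectory=True`` all models must share residue/atom topology.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format_hint]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    models = [_convert_gemmi_model(gm, i) for i, gm in enumerate(st)]
    if not models:
        raise ValueError(f"{path}: no coordinate models found")
    metadata = {
        "identifier": st.name,
        "source_format": "mmcif" if str(path).lower().endswith((".cif", ".mmcif")) else "pdb",
        "experiment_method": dict(st.info).get("_exptl.method"),
    }
    if metadata["experiment_method"] is None:
        warnings.warn(f"{path.name}: no experiment-method metadata; accepting file")
    ensemble = StructureEnsemble(models=models, metadata=metadata)
    if trajectory:
        _check_topology(ensemble)
    return ensemble


def _topology_signature(model: StructureModel):
    return [
        (r.chain_id, r.number, r.insertion_code, r.name, tuple(sorted(r.atom_names())))
        for r in model.iter_residues()
    ]


def _check_topology(ensemble: StructureEnsemble) -> None:
    ref = _topology_signature(ensemble.models[0])
    for m in ensemble.models[1:]:
        if _topology_signature(m) != ref:
            raise ValueError(
                f"topology mismatch: model {m.model_index} differs from model 0"
            )


def write_structure(ensemble: StructureEnsemble | StructureModel, path,
                    format: str = "pdb") -> None:
    """Write an ensemble (or single model) as PDB or mmCIF."""
    if isinstance(ensemble, StructureModel):
        ensemble = StructureEnsemble(models=[ensemble])
    st = gemmi.Structure()
    st.name = str(ensemble.metadata.get("identifier", "KINKSCAN"))
    for i, model in enumerate(ensemble.models):
        gmodel = gemmi.Model(i + 1)
        for chain_id, residues in model.chains.items():
            gchain = gemmi.Chain(chain_id)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
                if res.kind in ("dna_nucleotide", "rna_nucleotide",
                                "modified_nucleotide", "amino_acid"):
                    gres.het_flag = "A"
                else:
                    gres.het_flag = "H"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = atom.occupancy
                    if atom.altloc:
                        ga.altloc = atom.altloc
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    path = str(path)
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def truncate_sidechain(model: StructureModel,
                       residue_id: tuple[str, int, str],
                       target: str) -> StructureModel:
    """Return a copy of the model with one residue's sidechain truncated
    to ALA or GLY (the standard in-silico alanine/glycine mutation).

    Retained atoms keep their coordinates exactly; no geometry is built,
    so GLY -> ALA is refused.
    """
    target = target.upper()
    if target not in ("ALA", "GLY"):
        raise ValueError(f"target must be ALA or GLY, got {target!r}")
    chain_id, number, icode = residue_id
    new_model = copy.deepcopy(model)
    residue = new_model.find_residue(chain_id, number, icode)
    if residue is None:
        raise KeyError(f"residue {residue_id} not found")
    if residue.kind != "amino_acid":
        raise TypeError(f"residue {residue_id} ({residue.name}) is not an amino acid")
    keep = set(BACKBONE_ATOMS)
    if target == "ALA":
        if residue.atom("CB") is None:
            raise ValueError(
                f"residue {residue_id} has no CB atom; cannot truncate to ALA"
            )
        keep.add("CB")
    residue.atoms = [a for a in residue.atoms if a.name in keep]
    residue.name = target
    return new_model
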