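"""Phase I/II biotransformation enumeration and ionization-site expansion.

Candidate metabolite structures are generated by substructure-rewrite rules
(ester cleavage, hydroxylation, epoxidation, E/Z isomerization; sulfonation,
glucuronidation) applied with RDKit, deduplicated on canonical isomeric
SMILES, and optionally filtered against a target m/z for a set of adduct
types. Each surviving candidate records its transformation history so the
metabolization pathway it represents stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors
from rdkit import RDLogger

from .chem import ChemicalFormula, ion_mz, parse_formula, ppm_error

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "CandidateStructure",
    "IonizationVariant",
    "DGSM_SMILES",
    "PHASE1_RULES",
    "PHASE2_RULES",
    "enumerate_phase1",
    "enumerate_phase2",
    "enumerate_ionization",
    "filter_by_mass",
    "candidate_formula",
]

#: Digeraniol sinapoyl malate: sinapic acid esterified to the malate 2-OH,
#: both malate carboxyls esterified with (2E)-geranyl tails. Reconstructed
#: from the compound name (synthetic reference structure; no machine-readable
#: structure is distributed with the compound).
DGSM_SMILES = (
    "COc1cc(/C=C/C(=O)O[C@@H](CC(=O)OC/C=C(C)/CCC=C(C)C)"
    "C(=O)OC/C=C(C)/CCC=C(C)C)cc(OC)c1O"
)


@dataclass(frozen=True)
class CandidateStructure:
    """A candidate metabolite with its transformation provenance."""

    structure: str  # canonical isomeric SMILES
    history: tuple[str, ...] = ()
    parent_id: str | None = None
    matched_ion: str | None = None
    matched_mz: float | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise ValueError(f"unparsable SMILES {self.structure!r}")
        return m


@dataclass(frozen=True)
class IonizationVariant:
    """One (mode, site) ionization of a candidate structure."""

    candidate: CandidateStructure
    mode: str  # protonation | deprotonation | sodiation
    site_index: int  # atom index of the O/N site in the candidate mol


def _canonical(mol: Chem.Mol) -> str:
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse structure {smiles!r}")
    return mol


def candidate_formula(candidate: CandidateStructure | str) -> ChemicalFormula:
    """Molecular formula of a candidate (neutral form)."""
    smiles = candidate if isinstance(candidate, str) else candidate.structure
    raw = rdMolDescriptors.CalcMolFormula(_parse(smiles))
    # strip any charge suffix like "+" / "-" / "2-"
    raw = raw.rstrip("+-0123456789") if raw[-1] in "+-" else raw
    return parse_formula(raw)


# ---------------------------------------------------------------------------
# rewrite rules
# ---------------------------------------------------------------------------

# ester cleavage keeps the acid-side product (hydrolysis viewed from the
# acyl fragment); the alcohol-side leaving group is implicit
_ESTER_CLEAVAGE = AllChem.ReactionFromSmarts(
    "[C:1](=[O:2])[O:3][C;!$(C=O)]>>[C:1](=[O:2])[O:3][H]"
)
_EPOXIDATION = AllChem.ReactionFromSmarts(
    "[C;!$(C=O):1]=[C;!$(C=O):2]>>[C:1]1[C:2][O]1"
)
# sulfate-ester / sulfonate attachment at a hydroxyl or acid oxygen
_O_SULFONATION = AllChem.ReactionFromSmarts(
    "[O;X2;H1:1]>>[O:1]S(=O)(=O)O"
)
# C-sulfonation at an alkene carbon bearing an H
_C_SULFONATION = AllChem.ReactionFromSmarts(
    "[CX3;H1:1]=[C:2]>>[C:1](S(=O)(=O)O)=[C:2]"
)
# glucuronic acid attached through the anomeric carbon, both anomers
_GLUCURONIDATION_BETA = AllChem.ReactionFromSmarts(
    "[O;X2;H1:1]>>[O:1][C@@H]1O[C@H](C(=O)O)[C@@H](O)[C@H](O)[C@H]1O"
)
_GLUCURONIDATION_ALPHA = AllChem.ReactionFromSmarts(
    "[O;X2;H1:1]>>[O:1][C@H]1O[C@H](C(=O)O)[C@@H](O)[C@H](O)[C@H]1O"
)

#: aryl-conjugated enoate C=C — the photoactive sinapoyl-type double bond
_EZ_BOND_PATTERN = Chem.MolFromSmarts("c[CX3H1]=[CX3H1][CX3](=O)[OX2]")

#: aliphatic sp3 C-H positions eligible for hydroxylation (allylic included);
#: aromatic hydroxylation is enabled separately
_SP3_CH = Chem.MolFromSmarts("[CX4;!H0]")
_AROMATIC_CH = Chem.MolFromSmarts("[cH]")

_HYDROXYL = Chem.MolFromSmarts("[OX2H1][#6;!$(C=O)]")
_CARBOXYL_OH = Chem.MolFromSmarts("[OX2H1][CX3]=O")

PHASE1_RULES = ("ester_cleavage", "hydroxylation", "epoxidation", "EZ_isomerization")
PHASE2_RULES = ("sulfonation", "glucuronidation")


def _run_reaction(mol: Chem.Mol, rxn: AllChem.ChemicalReaction) -> set[str]:
    out: set[str] = set()
    for prods in rxn.RunReactants((mol,)):
        p = prods[0]
        try:
            Chem.SanitizeMol(p)
        except Exception:
            continue
        out.add(_canonical(p))
    return out


def _distinct_atom_sites(mol: Chem.Mol, pattern: Chem.Mol) -> list[int]:
    """One representative atom index per symmetry-equivalence class."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    seen: set[int] = set()
    sites: list[int] = []
    for match in mol.GetSubstructMatches(pattern):
        idx = match[0]
        if ranks[idx] not in seen:
            seen.add(ranks[idx])
            sites.append(idx)
    return sites


def _hydroxylate(mol: Chem.Mol, aromatic: bool = False) -> set[str]:
    out: set[str] = set()
    patterns = [_SP3_CH] + ([_AROMATIC_CH] if aromatic else [])
    for patt in patterns:
        for idx in _distinct_atom_sites(mol, patt):
            rw = Chem.RWMol(mol)
            o = rw.AddAtom(Chem.Atom(8))
            rw.AddBond(idx, o, Chem.BondType.SINGLE)
            rw.GetAtomWithIdx(idx).SetNoImplicit(False)
            try:
                Chem.SanitizeMol(rw)
            except Exception:
                continue
            out.add(_canonical(rw.GetMol()))
    return out


def _ez_isomerize(mol: Chem.Mol) -> set[str]:
    """Emit both configurations of each aryl-conjugated enoate double bond."""
    out: set[str] = set()
    matches = mol.GetSubstructMatches(_EZ_BOND_PATTERN)
    if not matches:
        return out
    for match in matches:
        a_ar, a1, a2, a_co = match[:4]
        for stereo in (Chem.BondStereo.STEREOTRANS, Chem.BondStereo.STEREOCIS):
            rw = Chem.RWMol(mol)
            bond = rw.GetBondBetweenAtoms(a1, a2)
            if bond.GetBeginAtomIdx() == a1:
                bond.SetStereoAtoms(a_ar, a_co)
            else:
                bond.SetStereoAtoms(a_co, a_ar)
            bond.SetStereo(stereo)
            Chem.SetDoubleBondNeighborDirections(rw)
            try:
                Chem.SanitizeMol(rw)
            except Exception:
                continue
            out.add(_canonical(rw.GetMol()))
    return out


def enumerate_phase1(
    parent: str | CandidateStructure,
    rules: set[str] | None = None,
    aromatic_hydroxylation: bool = False,
    parent_id: str | None = None,
) -> list[CandidateStructure]:
    """Apply phase-I functionalization rules to a parent structure.

    ``rules`` is a subset of :data:`PHASE1_RULES`. E/Z isomerization is
    applied after the other rules so that, e.g., ester-cleavage products are
    emitted in both configurations of the photoactive double bond. Results
    are deduplicated on canonical isomeric SMILES and sorted.
    """
    if isinstance(parent, CandidateStructure):
        parent_smiles, base_history = parent.structure, parent.history
    else:
        parent_smiles, base_history = parent, ()
    rules = set(PHASE1_RULES) if rules is None else set(rules)
    unknown = rules - set(PHASE1_RULES)
    if unknown:
        raise ValueError(f"unknown phase-I rules {sorted(unknown)}")
    mol = _parse(parent_smiles)

    produced: dict[str, tuple[str, ...]] = {}

    def emit(smiles: str, label: str, hist: tuple[str, ...]) -> None:
        if smiles not in produced:
            produced[smiles] = hist + (label,)

    if "ester_cleavage" in rules:
        for s in _run_reaction(mol, _ESTER_CLEAVAGE):
            emit(s, "ester_cleavage", base_history)
    if "hydroxylation" in rules:
        for s in _hydroxylate(mol, aromatic_hydroxylation):
            emit(s, "hydroxylation", base_history)
    if "epoxidation" in rules:
        for s in _run_reaction(mol, _EPOXIDATION):
            emit(s, "epoxidation", base_history)
    if "EZ_isomerization" in rules:
        # expand every product (and the parent, if it was the only input)
        targets = dict(produced) if produced else {parent_smiles: base_history}
        for smi, hist in targets.items():
            for s in _ez_isomerize(_parse(smi)):
                if s not in produced:
                    produced[s] = hist + ("EZ_isomerization",)

    return [
        CandidateStructure(s, history=h, parent_id=parent_id)
        for s, h in sorted(produced.items())
    ]


def enumerate_phase2(
    parent: str | CandidateStructure,
    rules: set[str] | None = None,
    sites: set[str] | None = None,
    anomeric_enumeration: bool = True,
    parent_id: str | None = None,
) -> list[CandidateStructure]:
    """Apply phase-II conjugation rules (sulfonation, glucuronidation).

    ``sites`` restricts attachment points: any subset of ``hydroxyl``,
    ``carboxylic_acid`` and ``alkene_carbon`` (the last applies to
    sulfonation only). Glucuronidation emits both anomeric configurations
    when ``anomeric_enumeration`` is on.
    """
    if isinstance(parent, CandidateStructure):
        parent_smiles, base_history = parent.structure, parent.history
    else:
        parent_smiles, base_history = parent, ()
    rules = set(PHASE2_RULES) if rules is None else set(rules)
    unknown = rules - set(PHASE2_RULES)
    if unknown:
        raise ValueError(f"unknown phase-II rules {sorted(unknown)}")
    sites = {"hydroxyl", "carboxylic_acid", "alkene_carbon"} if sites is None else set(sites)
    mol = _parse(parent_smiles)

    o_patterns = []
    if "hydroxyl" in sites:
        o_patterns.append(_HYDROXYL)
    if "carboxylic_acid" in sites:
        o_patterns.append(_CARBOXYL_OH)

    def o_restricted(rxn) -> set[str]:
        """Run an O-attachment reaction with non-allowed oxygens protected."""
        if not o_patterns:
            return set()
        allowed: set[int] = set()
        for patt in o_patterns:
            allowed.update(m[0] for m in mol.GetSubstructMatches(patt))
        work = Chem.Mol(mol)
        for atom in work.GetAtoms():
            if atom.GetSymbol() == "O" and atom.GetIdx() not in allowed:
                atom.SetProp("_protected", "1")
        return _run_reaction(work, rxn)

    produced: dict[str, tuple[str, ...]] = {}

    def emit(smiles_set: set[str], label: str) -> None:
        for s in smiles_set:
            if s not in produced:
                produced[s] = base_history + (label,)

    if "sulfonation" in rules:
        emit(o_restricted(_O_SULFONATION), "sulfonation")
        if "alkene_carbon" in sites:
            emit(_run_reaction(mol, _C_SULFONATION), "sulfonation")
    if "glucuronidation" in rules:
        rxns = [_GLUCURONIDATION_BETA]
        if anomeric_enumeration:
            rxns.append(_GLUCURONIDATION_ALPHA)
        for rxn in rxns:
            emit(o_restricted(rxn), "glucuronidation")

    return [
        CandidateStructure(s, history=h, parent_id=parent_id)
        for s, h in sorted(produced.items())
    ]


_ION_MODES = {"protonation": "[M+H]+", "deprotonation": "[M-H]-", "sodiation": "[M+Na]+"}


def enumerate_ionization(
    candidate: CandidateStructure | str,
    modes: set[str] | None = None,
) -> list[IonizationVariant]:
    """One ionization variant per (mode, symmetry-distinct O/N site).

    Protonation and sodiation consider every O and N atom; deprotonation
    only sites carrying a hydrogen. Symmetry-equivalent atoms are merged by
    canonical atom ranking.
    """
    cand = (
        candidate
        if isinstance(candidate, CandidateStructure)
        else CandidateStructure(_canonical(_parse(candidate)))
    )
    modes = set(_ION_MODES) if modes is None else set(modes)
    unknown = modes - set(_ION_MODES)
    if unknown:
        raise ValueError(f"unknown ionization modes {sorted(unknown)}")
    mol = cand.mol()
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    variants: list[IonizationVariant] = []
    for mode in sorted(modes):
        seen: set[int] = set()
        for atom in mol.GetAtoms():
            if atom.GetSymbol() not in ("O", "N"):
                continue
            if mode == "deprotonation" and atom.GetTotalNumHs() == 0:
                continue
            if ranks[atom.GetIdx()] in seen:
                continue
            seen.add(ranks[atom.GetIdx()])
            variants.append(IonizationVariant(cand, mode, atom.GetIdx()))
    return variants


def filter_by_mass(
    candidates: list[CandidateStructure],
    target_mz: float,
    ion_types: list[str] = ("[M+Na]+",),
    ppm_tol: float = 10.0,
) -> list[CandidateStructure]:
    """Keep candidates whose ion m/z matches the target within ``ppm_tol``.

    Each survivor records the matching ion type and its computed m/z.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    out: list[CandidateStructure] = []
    for cand in candidates:
        formula = candidate_formula(cand)
        for ion_type in ion_types:
            mz = ion_mz(formula, ion_type)
            if abs(ppm_error(target_mz, mz)) <= ppm_tol:
                out.append(replace(cand, matched_ion=ion_type, matched_mz=mz))
                break
    return out
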