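"""Toy transform templates: substructure-pattern rewrites over reactants.

Each :class:`TransformTemplate` wraps an RDKit reaction SMARTS plus the slot
patterns its reactants must match, an arity, and the reaction-class code it
belongs to. The curated :data:`TEMPLATE_LIBRARY` spans three top-level
classes with subclasses, including two "sibling" aryl-coupling subclasses
that differ only in the leaving group (for sibling-ablation studies) and a
single-/double-addition pair of organomagnesium additions to esters whose
composition property (single addition applied twice equals the double
addition) backs multi-round iterated-prediction experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import rdChemReactions



class TemplateNoMatchError(ValueError):
    """Substrates do not match the template's slot patterns."""


@dataclass(frozen=True)
class TransformTemplate:
    """A deterministic reactants -> products rewrite.

    Parameters
    ----------
    transform_id : str
        Unique name, used as the ``transform`` string planted on generated
        records and looked up by the retrieval baseline.
    smarts : str
        RDKit reaction SMARTS; reactant templates double as slot patterns.
    class_code : str
        The hierarchical reaction-class code this transform realizes.
    agents : tuple of str
        Fixed agent SMILES recorded on reactions using this transform.
    """

    transform_id: str
    smarts: str
    class_code: str
    agents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rxn = rdChemReactions.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise ValueError(f"invalid reaction SMARTS: {self.smarts!r}")
        object.__setattr__(self, "_rxn", rxn)
        slots = tuple(rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates()))
        object.__setattr__(self, "_slots", slots)
        object.__setattr__(self, "_memo", {})

    @property
    def arity(self) -> int:
        return len(self._slots)  # type: ignore[attr-defined]

    def slot_matches(self, mol: Chem.Mol, slot: int) -> bool:
        return mol.HasSubstructMatch(self._slots[slot])  # type: ignore[attr-defined]

    def _run(self, mols: Sequence[Chem.Mol]) -> set[str]:
        """All distinct canonical product sets from one slot assignment."""
        out: set[str] = set()
        for prods in self._rxn.RunReactants(tuple(mols)):  # type: ignore[attr-defined]
            try:
                smis = []
                for p in prods:
                    Chem.SanitizeMol(p)
                    smis.append(Chem.MolToSmiles(p))
                out.add(".".join(sorted(smis)))
            except Exception:  # noqa: BLE001 — invalid enumerations are skipped
                continue
        return out

    def candidate_products(self, substrates: Sequence[str]) -> list[str]:
        """Apply the template to ``substrates`` in every slot assignment.

        Each slot is filled by a distinct substrate; when more substrates
        are supplied than the template has slots, the remainder act as
        spectators and do not appear in the products. Returns the sorted
        list of distinct canonical product-set SMILES (dot-joined), or an
        empty list when no assignment matches.
        """
        key = tuple(substrates)
        memo: dict = self._memo  # type: ignore[attr-defined]
        if key in memo:
            return memo[key]
        if len(substrates) < self.arity:
            memo[key] = []
            return []
        mols = [Chem.MolFromSmiles(s) for s in substrates]
        if any(m is None for m in mols):
            raise TemplateNoMatchError(f"unparseable substrate among {substrates}")
        out: set[str] = set()
        for perm in set(itertools.permutations(range(len(mols)), self.arity)):
            ordered = [mols[i] for i in perm]
            if all(self.slot_matches(m, i) for i, m in enumerate(ordered)):
                out |= self._run(ordered)
        result = sorted(out)
        memo[key] = result
        return result

    def apply(self, substrates: Sequence[str]) -> list[str]:
        """As :meth:`candidate_products` but the first (canonically smallest)
        product set is authoritative; raises when nothing matches."""
        cands = self.candidate_products(substrates)
        if not cands:
            raise TemplateNoMatchError(
                f"{self.transform_id}: no slot assignment of {list(substrates)} matches"
            )
        return cands[0].split(".")

    def applicable(self, substrates: Sequence[str]) -> bool:
        try:
            return bool(self.candidate_products(substrates))
        except TemplateNoMatchError:
            return False


_PD = "c1ccc(P(c2ccccc2)c2ccccc2)cc1"  # triphenylphosphine stand-in ligand

TEMPLATE_LIBRARY: tuple[TransformTemplate, ...] = (
    TransformTemplate(
        "amine_alkylation",
        "[NX3;H2:1][CX4:2].[CX4:3][Br]>>[C:3][NX3;H1:1][C:2]",
        class_code="1.6.1",
        agents=("O=C([O-])[O-]", "[K+]"),
    ),
    TransformTemplate(
        "williamson_ether",
        "[c:1][OX2H:2].[CX4:3][Br]>>[c:1][O:2][C:3]",
        class_code="1.7.1",
        agents=("O=C([O-])[O-]", "[K+]"),
    ),
    TransformTemplate(
        "amide_coupling",
        "[C:1](=[O:2])[OX2H].[NX3;H2:3]>>[C:1](=[O:2])[N:3]",
        class_code="2.1.1",
        agents=("CCN=C=NCCCN(C)C",),
    ),
    TransformTemplate(
        "fischer_esterification",
        "[C:1](=[O:2])[OX2H].[OX2H:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]",
        class_code="2.1.2",
        agents=("OS(=O)(=O)O",),
    ),
    TransformTemplate(
        "suzuki_bromo",
        "[c:1][Br].[c:2]B(O)O>>[c:1][c:2]",
        class_code="3.1.1",
        agents=("[Pd]", _PD),
    ),
    TransformTemplate(
        "suzuki_chloro",
        "[c:1][Cl].[c:2]B(O)O>>[c:1][c:2]",
        class_code="3.1.2",
        agents=("[Pd]", _PD),
    ),
    TransformTemplate(
        "buchwald_hartwig",
        "[c:1][Br].[NX3;H2:2]>>[c:1][NX3;H1:2]",
        class_code="3.2.1",
        agents=("[Pd]", "CC(C)c1cc(C(C)C)c(-c2ccccc2P(C2CCCCC2)C2CCCCC2)c(C(C)C)c1"),
    ),
    TransformTemplate(
        "grignard_ester_single",
        "[C:1](=[O:2])[OX2][CH3].[#6:3][Mg][Br]>>[C:1](=[O:2])[#6:3]",
        class_code="10.1.1",
        agents=("C1CCOC1",),
    ),
    TransformTemplate(
        "grignard_ketone_addition",
        "[#6:4][CX3:1](=[O:2])[#6:5].[#6:3][Mg][Br]>>[#6:4][C:1]([OX2H:2])([#6:5])[#6:3]",
        class_code="10.1.2",
        agents=("C1CCOC1",),
    ),
    TransformTemplate(
        "grignard_ester_double",
        "[C:1](=[O:2])[OX2][CH3].[#6:3][Mg][Br].[#6:4][Mg][Br]"
        ">>[C:1]([OX2H:2])([#6:3])[#6:4]",
        class_code="10.2.1",
        agents=("C1CCOC1",),
    ),
)

TEMPLATES_BY_ID: dict[str, TransformTemplate] = {
    t.transform_id: t for t in TEMPLATE_LIBRARY
}
TEMPLATES_BY_CLASS: dict[str, TransformTemplate] = {
    t.class_code: t for t in TEMPLATE_LIBRARY
}


def get_template(transform_id: str) -> TransformTemplate:
    try:
        return TEMPLATES_BY_ID[transform_id]
    except KeyError:
        raise KeyError(f"unknown transform_id {transform_id!r}") from None


def apply_template(template: TransformTemplate | str, substrates: Sequence[str]) -> list[str]:
    """Apply a template (by object or id) to substrates; explicit no-match error."""
    if isinstance(template, str):
        template = get_template(template)
    return template.apply(substrates)
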