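"""Pharmacophore typing: one coarse chemical label per heavy atom.

Labels follow the DOCK pharmacophore-similarity alphabet — positive (P),
negative (N), donor-acceptor (DA), donor (D), acceptor (A), aromatic (AR),
hydrophobic (H), polar (PL), halogen (HA) — extended with a metal-ion label
(MI) for isolated biometal ions.  Assignment scans an ordered rule table
(shipped as a plain-text resource, see ``data/pharmacophore_rules.txt``)
matching each atom's SYBYL type and bonded neighbourhood; the first matching
rule wins.  Rules are ordered from most specific to generic, so e.g. a
carboxylate oxygen is N(egative) before the generic oxygen A(cceptor) rule
can fire.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .structures import Atom, METAL_ELEMENTS, Molecule, StructureError

log = logging.getLogger(__name__)

#: Fixed label enumeration; feature-vector bin order follows this sequence.
DEFAULT_ALPHABET: tuple[str, ...] = (
    "P", "N", "DA", "D", "A", "AR", "H", "PL", "HA", "MI"
)
#: Nine-type mode (metal-ion label dropped).
ALPHABET_9: tuple[str, ...] = DEFAULT_ALPHABET[:-1]

#: Label applied to heavy atoms no rule covers (e.g. B, Se).
FALLBACK_LABEL = "PL"

# Expected connection counts per SYBYL type, used to impute implicit
# hydrogens when a structure carries no explicit ones.  sp2/aromatic N with
# two ring bonds is taken as pyridine-like (no implied H); pyrrole-type
# nitrogens therefore need explicit hydrogens to type as donors.
_EXPECTED_CONNECTIONS = {
    "C.3": 4, "C.2": 3, "C.ar": 3, "C.1": 2, "C.cat": 3,
    "N.4": 4, "N.3": 3, "N.am": 3, "N.pl3": 3, "N.2": 2, "N.ar": 2, "N.1": 1,
    "O.3": 2, "O": 2, "O.2": 1, "O.co2": 1, "O.spc": 2, "O.t3p": 2,
    "S.3": 2, "S": 2, "S.2": 1, "P.3": 3,
}


# ---------------------------------------------------------------------------
# rule model and pattern parser
# ---------------------------------------------------------------------------

@dataclass
class NeighborSpec:
    """An atom pattern: alternative type names plus bond clauses."""
    types: tuple[str, ...]
    required: list["Clause"] = field(default_factory=list)
    forbidden: list["Clause"] = field(default_factory=list)


@dataclass
class Clause:
    """A bonded-neighbour constraint: at least/at most ``count`` matches."""
    count: Optional[int]
    spec: NeighborSpec


@dataclass
class TypingRule:
    label: str
    pattern: str
    spec: NeighborSpec
    priority: int


_TOKEN_RE = re.compile(r"\(|\)|\[|\]|\*|\d+|[A-Za-z][A-Za-z0-9.+]*")


def _parse_clause(tokens: list[str]) -> tuple[Clause, bool]:
    opener = tokens.pop(0)
    forbidden = opener == "["
    closer = "]" if forbidden else ")"
    count = None
    if tokens and tokens[0].isdigit():
        count = int(tokens.pop(0))
    # types: a group "(A or B)" (only legal immediately here), "*", or a name
    if tokens and tokens[0] == "(":
        tokens.pop(0)
        types = [tokens.pop(0)]
        while tokens and tokens[0] == "or":
            tokens.pop(0)
            types.append(tokens.pop(0))
        if not tokens or tokens.pop(0) != ")":
            raise StructureError("unclosed type group in typing rule")
        spec = NeighborSpec(tuple(types))
    else:
        spec = NeighborSpec((tokens.pop(0),))
    while tokens and tokens[0] in "([":
        sub, sub_forbidden = _parse_clause(tokens)
        (spec.forbidden if sub_forbidden else spec.required).append(sub)
    if not tokens or tokens.pop(0) != closer:
        raise StructureError("unbalanced clause in typing rule")
    return Clause(count, spec), forbidden


def parse_pattern(pattern: str) -> NeighborSpec:
    tokens = _TOKEN_RE.findall(pattern)
    if not tokens:
        raise StructureError(f"empty typing pattern {pattern!r}")
    spec = NeighborSpec((tokens.pop(0),))
    while tokens:
        clause, forbidden = _parse_clause(tokens)
        (spec.forbidden if forbidden else spec.required).append(clause)
    return spec


def load_rules(path=None) -> list[TypingRule]:
    """Load the ordered typing-rule table (default: the packaged resource)."""
    if path is None:
        text = (resources.files("dockrf.data") / "pharmacophore_rules.txt").read_text()
    else:
        text = open(path).read()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, _, pattern = line.partition("\t")
        label, pattern = label.strip(), pattern.strip()
        if not pattern:
            raise StructureError(f"malformed rule line {line!r}")
        rules.append(TypingRule(label, pattern, parse_pattern(pattern), len(rules)))
    return rules


_DEFAULT_RULES: Optional[list[TypingRule]] = None


def default_rules() -> list[TypingRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _type_matches(type_name: str, atom: Atom) -> bool:
    if type_name == "*":
        return True
    if type_name == "H":
        return atom.is_hydrogen
    if "." in type_name:
        return atom.sybyl_type == type_name
    return atom.element == type_name


def _spec_matches_implied_h(spec: NeighborSpec) -> bool:
    return (not spec.required and not spec.forbidden
            and any(t in ("*", "H") for t in spec.types))


def _implied_h(atom: Atom, mol: Molecule) -> int:
    if mol.has_explicit_hydrogens or atom.is_hydrogen:
        return 0
    expected = _EXPECTED_CONNECTIONS.get(atom.sybyl_type)
    if expected is None:
        expected = _EXPECTED_CONNECTIONS.get(atom.element, 0)
    return max(0, expected - len(atom.neighbor_indices))


def _match_spec(atom: Atom, mol: Molecule, spec: NeighborSpec,
                parent: Optional[Atom]) -> bool:
    if not any(_type_matches(t, atom) for t in spec.types):
        return False
    neighbors = mol.neighbors(atom)
    implied = _implied_h(atom, mol)
    matched: set[int] = set()
    implied_left = implied
    # Required clauses count every bond, including the one back to the parent.
    for cl in spec.required:
        cands = [n for n in neighbors if _match_spec(n, mol, cl.spec, atom)]
        have = len(cands)
        if _spec_matches_implied_h(cl.spec):
            have += implied_left
        if have < (cl.count or 1):
            return False
        matched.update(n.index for n in cands)
        if _spec_matches_implied_h(cl.spec):
            implied_left = 0
    # Forbidden clauses ignore the bond to the parent atom.
    for cl in spec.forbidden:
        others = [n for n in neighbors if parent is None or n.index != parent.index]
        if cl.count is not None:
            have = sum(_match_spec(n, mol, cl.spec, atom) for n in others)
            if _spec_matches_implied_h(cl.spec):
                have += implied_left
            if have >= cl.count:
                return False
        else:
            rem = [n for n in others if n.index not in matched]
            if any(_match_spec(n, mol, cl.spec, atom) for n in rem):
                return False
            if _spec_matches_implied_h(cl.spec) and implied_left > 0:
                return False
    return True


def assign_pharmacophore(atom: Atom, mol: Molecule,
                         rules: Optional[list[TypingRule]] = None,
                         alphabet: tuple[str, ...] = DEFAULT_ALPHABET
                         ) -> Optional[str]:
    """Label one atom; hydrogens get ``None``.

    Isolated biometal ions take MI (when the alphabet has it); otherwise the
    first matching rule in table order wins; uncovered heavy atoms fall back
    to PL with a logged warning.
    """
    if atom.is_hydrogen:
        return None
    if rules is None:
        rules = default_rules()
    if (atom.element in METAL_ELEMENTS and not atom.neighbor_indices
            and "MI" in alphabet):
        return "MI"
    for rule in rules:
        if rule.label not in alphabet:
            continue
        if _match_spec(atom, mol, rule.spec, parent=None):
            return rule.label
    log.warning("no typing rule for atom %s (%s/%s); falling back to %s",
                atom.index, atom.element, atom.sybyl_type, FALLBACK_LABEL)
    return FALLBACK_LABEL


def assign_molecule(mol: Molecule, rules: Optional[list[TypingRule]] = None,
                    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
                    ) -> list[Optional[str]]:
    """Label every atom of a molecule; caches the result on the molecule."""
    labels = [assign_pharmacophore(a, mol, rules, alphabet) for a in mol.atoms]
    mol.pharmacophores = labels
    return labels


def count_labels(mol: Molecule,
                 alphabet: tuple[str, ...] = DEFAULT_ALPHABET) -> dict[str, int]:
    """Tally labels over heavy atoms (typing the molecule if needed)."""
    if mol.pharmacophores is None:
        assign_molecule(mol, alphabet=alphabet)
    counts = {label: 0 for label in alphabet}
    for lab in mol.pharmacophores:
        if lab is not None:
            counts[lab] = counts.get(lab, 0) + 1
    return counts
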