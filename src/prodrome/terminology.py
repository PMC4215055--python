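"""Terminologies that define the depression phenotype.

Three ingredients: a seed depression term set expanded through an is-a
ontology, an antidepressant ingredient set derived from a drug-indication
table, and the negation / family-history filters applied to annotated text
mentions.  Concept identifiers are opaque strings; the toy terminology
builders at the bottom stand in for the licensed vocabularies (UMLS,
RxNorm, Medi-Span) a production deployment would plug in here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# provenance tags
SEED = "seed"
REMOVED = "removed_by_filter"


def _expansion_tag(round_no: int) -> str:
    return f"expansion_round_{round_no}"


@dataclass
class OntologyGraph:
    """Directed is-a graph: edges point child -> parent."""

    nodes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.nodes or parent not in self.nodes:
                raise ValueError(f"edge ({child}, {parent}) references unknown node")
        self._check_acyclic()
        self._children: dict[str, list[str]] = {}
        for child, parent in sorted(self.edges):
            self._children.setdefault(parent, []).append(child)

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on child->parent edges
        indeg = {n: 0 for n in self.nodes}
        for child, _parent in self.edges:
            indeg[child] += 0  # ensure key
        out = {n: [] for n in self.nodes}
        for child, parent in self.edges:
            out[child].append(parent)
            indeg[parent] = indeg.get(parent, 0) + 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for m in out[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        if seen != len(self.nodes):
            raise ValueError("ontology contains an is-a cycle")

    def children(self, concept: str) -> list[str]:
        """Concepts one inverse is-a step below ``concept``."""
        return list(self._children.get(concept, []))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "OntologyGraph":
        edges = set(edges)
        nodes = {c for c, _ in edges} | {p for _, p in edges}
        return cls(nodes=nodes, edges=edges)

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "OntologyGraph":
        """Read a two-column (child, parent) TSV edge list."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"],
                            dtype=str, comment="#")
        return cls.from_edges(zip(frame["child"], frame["parent"]))


@dataclass
class TermSet:
    """A concept set with per-concept provenance (seed, expansion round, or
    removed_by_filter)."""

    concepts: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_seed(cls, seed: Iterable[str]) -> "TermSet":
        seed = set(seed)
        return cls(concepts=set(seed), provenance={c: SEED for c in seed})

    def __contains__(self, concept: str) -> bool:
        return concept in self.concepts

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(set(self.provenance) | self.concepts)
        return pd.DataFrame(
            {"concept": rows,
             "provenance": [self.provenance.get(c, "") for c in rows]}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def expand_seed_terms(seed: TermSet, ontology: OntologyGraph, rounds: int = 2) -> TermSet:
    """Expand a seed term set downward through is-a: after round k the set
    contains every concept reachable from a seed by at most k inverse is-a
    steps.  Two rounds is the default; more rounds approach the transitive
    closure and the expansion is idempotent once the reachable set is
    exhausted.

    Provenance records the round at which each concept first entered.
    """
    unknown = sorted(c for c in seed.concepts if c not in ontology.nodes)
    if unknown:
        raise KeyError(f"seed concept(s) not in ontology: {', '.join(unknown)}")
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    concepts = set(seed.concepts)
    provenance = dict(seed.provenance)
    frontier = set(seed.concepts)
    for k in range(1, rounds + 1):
        new = set()
        for concept in frontier:
            for child in ontology.children(concept):
                if child not in concepts:
                    new.add(child)
        for child in new:
            provenance[child] = _expansion_tag(k)
        concepts |= new
        frontier = new
        if not frontier:
            break
    return TermSet(concepts=concepts, provenance=provenance)


def filter_terms(terms: TermSet, blocklist: Iterable[str]) -> TermSet:
    """Drop blocklisted concepts (the curated false-positive filter),
    tagging them ``removed_by_filter``."""
    blocklist = set(blocklist)
    concepts = terms.concepts - blocklist
    provenance = dict(terms.provenance)
    for concept in terms.concepts & blocklist:
        provenance[concept] = REMOVED
    return TermSet(concepts=concepts, provenance=provenance)


@dataclass
class DrugIndicationTable:
    """Rows of (drug id, ingredient set, primary indication set)."""

    rows: list[tuple[str, frozenset[str], frozenset[str]]]

    def __post_init__(self) -> None:
        for drug, ingredients, _ in self.rows:
            if not ingredients:
                raise ValueError(f"drug {drug} has an empty ingredient set")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugIndicationTable":
        """CSV columns: drug_id, ingredients (semicolon-joined), indications
        (semicolon-joined)."""
        frame = pd.read_csv(path, dtype=str)
        rows = [
            (
                row.drug_id,
                frozenset(str(row.ingredients).split(";")),
                frozenset(str(row.indications).split(";")),
            )
            for row in frame.itertuples()
        ]
        return cls(rows=rows)

    def indications(self) -> set[str]:
        out: set[str] = set()
        for _, _, inds in self.rows:
            out |= inds
        return out


def derive_antidepressant_ingredients(
    table: DrugIndicationTable, indication: str
) -> set[str]:
    """Ingredients of drugs indicated for the target condition, minus any
    ingredient that also appears in a drug with a different primary
    indication.  The subtraction keeps only ingredients specific to the
    condition, so a mention is unambiguous evidence of its treatment.
    """
    if indication not in table.indications():
        raise KeyError(f"indication {indication!r} not present in drug table")
    positives: set[str] = set()
    negatives: set[str] = set()
    for _drug, ingredients, indications in table.rows:
        if indication in indications:
            positives |= ingredients
        if indications - {indication}:
            negatives |= ingredients
    return positives - negatives


@dataclass(frozen=True)
class AnnotatedTerm:
    """A text-derived concept mention with its annotation flags."""

    concept: str
    negated: bool = False
    family_history: bool = False
    date: int = 0


def usable_annotations(events: Sequence[AnnotatedTerm]) -> list[AnnotatedTerm]:
    """Mentions that assert the concept for the patient: neither negated nor
    attributed to family history.  Order preserved."""
    return [e for e in events if not e.negated and not e.family_history]


# ---------------------------------------------------------------------------
# ICD-9 depression code set

#: Depression ICD-9 families. Major-depressive families 296.2x / 296.3x match
#: on the first four digits (the fifth digit encodes episode severity).
DEPRESSION_ICD9_FAMILIES = ("296.2", "296.3")
DEPRESSION_ICD9_EXACT = ("296.82", "298.0", "300.4", "311")


def expand_icd9_brackets(pattern: str) -> list[str]:
    """Expand a bracketed family like ``296.2[0-6]`` to explicit codes."""
    if "[" not in pattern:
        return [pattern]
    head, rest = pattern.split("[", 1)
    span, tail = rest.split("]", 1)
    lo, hi = span.split("-") if "-" in span else (span.replace("–", "-").split("-"))
    return [f"{head}{d}{tail}" for d in range(int(lo), int(hi) + 1)]


def default_depression_icd9_codes() -> set[str]:
    """The explicit depression code enumeration: 296.2x / 296.3x (x in 0-6),
    atypical depressive disorder, depressive psychosis, dysthymia, and
    depressive disorder NEC."""
    codes: set[str] = set(DEPRESSION_ICD9_EXACT)
    for fam in DEPRESSION_ICD9_FAMILIES:
        codes.update(expand_icd9_brackets(f"{fam}[0-6]"))
    return codes


def canonical_icd9(code: str) -> str:
    """Truncate the fifth digit of major-depressive-family codes so 296.30
    and 296.3 compare equal; other codes pass through unchanged."""
    for fam in DEPRESSION_ICD9_FAMILIES:
        if code.startswith(fam):
            return fam
    return code


def is_depression_icd9(code: str, code_set: set[str] | None = None) -> bool:
    if code_set is None:
        code_set = default_depression_icd9_codes()
    canonical_set = {canonical_icd9(c) for c in code_set}
    return canonical_icd9(code) in canonical_set


# ---------------------------------------------------------------------------
# toy terminologies (stand-ins for UMLS / RxNorm / Medi-Span lookups)

DEPRESSION_INDICATION = "depression"

#: Seed depression disorder concepts.
DEPRESSION_SEED_TERMS = (
    "depressive_disorder",
    "major_depressive_disorder",
    "depression_adverse_event",
    "depressive_disorder_nec",
)


def toy_ontology() -> OntologyGraph:
    """A small is-a hierarchy under the seed depression concepts, plus
    unrelated branches that must never enter the expansion."""
    edges = [
        ("major_depressive_disorder", "depressive_disorder"),
        ("dysthymia", "depressive_disorder"),
        ("seasonal_affective_disorder", "depressive_disorder"),
        ("mdd_single_episode", "major_depressive_disorder"),
        ("mdd_recurrent", "major_depressive_disorder"),
        ("postpartum_depression", "major_depressive_disorder"),
        ("psychotic_depression", "mdd_single_episode"),
        ("mood_disorder", "mental_disorder"),
        ("depressive_disorder", "mood_disorder"),
        ("bipolar_disorder", "mood_disorder"),
        ("anxiety_disorder", "mental_disorder"),
        ("generalized_anxiety", "anxiety_disorder"),
        ("depression_adverse_event", "adverse_event"),
        ("depressive_disorder_nec", "depressive_disorder"),
    ]
    return OntologyGraph.from_edges(edges)


def toy_drug_table() -> DrugIndicationTable:
    """A miniature drug-indication table: SSRI-like antidepressants whose
    ingredients are depression-specific, plus drugs whose ingredients cross
    over to other primary indications (and are therefore excluded)."""
    rows = [
        ("rx_fluoxetine", frozenset({"fluoxetine"}), frozenset({DEPRESSION_INDICATION})),
        ("rx_sertraline", frozenset({"sertraline"}), frozenset({DEPRESSION_INDICATION})),
        ("rx_citalopram", frozenset({"citalopram"}), frozenset({DEPRESSION_INDICATION})),
        ("rx_venlafaxine", frozenset({"venlafaxine"}), frozenset({DEPRESSION_INDICATION})),
        ("rx_mirtazapine", frozenset({"mirtazapine"}), frozenset({DEPRESSION_INDICATION})),
        # amitriptyline also carries a neuropathic-pain indication -> excluded
        ("rx_amitriptyline", frozenset({"amitriptyline"}),
         frozenset({DEPRESSION_INDICATION, "neuropathic_pain"})),
        # bupropion also marketed for smoking cessation -> excluded
        ("rx_bupropion", frozenset({"bupropion"}),
         frozenset({DEPRESSION_INDICATION, "smoking_cessation"})),
        ("rx_ibuprofen", frozenset({"ibuprofen"}), frozenset({"pain"})),
    ]
    return DrugIndicationTable(rows=rows)


def default_depression_terms(rounds: int = 2) -> TermSet:
    """Seed terms expanded ``rounds`` steps through the toy ontology."""
    seed = TermSet.from_seed(DEPRESSION_SEED_TERMS)
    return expand_seed_terms(seed, toy_ontology(), rounds=rounds)


def default_antidepressant_ingredients() -> set[str]:
    return derive_antidepressant_ingredients(toy_drug_table(), DEPRESSION_INDICATION)
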