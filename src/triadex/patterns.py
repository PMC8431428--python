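"""Inheritance-mode classification of triad expression patterns.

A gene's behaviour in a (female parent, male parent, F1 hybrid) triad is
summarised by three pairwise relations: female vs male, hybrid vs female
and hybrid vs male.  Each relation is three-valued (first higher, second
higher, or no significant difference), giving 27 possible triples.  The
triples that are internally consistent map onto 12 classes grouped into
five biological categories:

* **additive** (classes 1-2): the hybrid sits strictly between two
  differing parents, significantly different from both.
* **ELD-F / ELD-M** (classes 3-4 / 5-6): expression-level dominance; the
  parents differ while the hybrid is statistically indistinguishable from
  the female (ELD-F) or male (ELD-M) parent.
* **down-overdominant** (classes 7-9): the hybrid is significantly below
  both parents.
* **up-overdominant** (classes 10-12): the hybrid is significantly above
  both parents.

Genes with no significant difference in any of the three comparisons are
*conserved*; triples that match no class (e.g. H=F and H<M while F=M) are
*unclassified*.  Within a category the class index encodes the parental
sub-pattern; parents-equal overdominance is assigned the first index of
its category (7 down, 10 up).
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

#: relation symbols: ">" first sample-group higher, "<" second higher, "=" no difference
RELATIONS = (">", "<", "=")

CONSERVED = "conserved"
UNCLASSIFIED = "unclassified"

#: class index -> category label
CLASS_CATEGORY: Dict[object, str] = {
    1: "additive",
    2: "additive",
    3: "ELD-F",
    4: "ELD-F",
    5: "ELD-M",
    6: "ELD-M",
    7: "down-overdominant",
    8: "down-overdominant",
    9: "down-overdominant",
    10: "up-overdominant",
    11: "up-overdominant",
    12: "up-overdominant",
    CONSERVED: CONSERVED,
    UNCLASSIFIED: UNCLASSIFIED,
}

CATEGORIES = (
    "additive",
    "ELD-F",
    "ELD-M",
    "down-overdominant",
    "up-overdominant",
)

# (rel_FM, rel_HF, rel_HM) -> class.  rel_FM is the F:M relation (">" = F
# higher), rel_HF the H:F relation (">" = H higher), rel_HM the H:M relation.
_RULE_TABLE: Dict[Tuple[str, str, str], object] = {
    (">", "<", ">"): 1,   # additive, female high: F > H > M
    ("<", ">", "<"): 2,   # additive, female low:  M > H > F
    (">", "=", ">"): 3,   # ELD-F, expression high (follows higher female)
    ("<", "=", "<"): 4,   # ELD-F, expression low
    ("<", ">", "="): 5,   # ELD-M, expression high (follows higher male)
    (">", "<", "="): 6,   # ELD-M, expression low
    ("=", "<", "<"): 7,   # down-OD, parents equal
    (">", "<", "<"): 8,   # down-OD, F > M
    ("<", "<", "<"): 9,   # down-OD, F < M
    ("=", ">", ">"): 10,  # up-OD, parents equal
    (">", ">", ">"): 11,  # up-OD, F > M
    ("<", ">", ">"): 12,  # up-OD, F < M
    ("=", "=", "="): CONSERVED,
}

#: parent-relabelling (F <-> M) permutation of class labels
SWAP_MAP: Dict[object, object] = {
    1: 2, 2: 1,
    3: 5, 5: 3,
    4: 6, 6: 4,
    7: 7,
    8: 9, 9: 8,
    10: 10,
    11: 12, 12: 11,
    CONSERVED: CONSERVED,
    UNCLASSIFIED: UNCLASSIFIED,
}


def classify_gene(rel_fm: str, rel_hf: str, rel_hm: str):
    """Map one call triple to its class label.

    Parameters
    ----------
    rel_fm, rel_hf, rel_hm
        Relations female:male, hybrid:female and hybrid:male, each one of
        ``">"`` (first higher), ``"<"`` (second higher) or ``"="``.

    Returns
    -------
    int or str
        A class index in 1..12, ``"conserved"`` or ``"unclassified"``.
    """
    for rel in (rel_fm, rel_hf, rel_hm):
        if rel not in RELATIONS:
            raise ValueError(f"invalid relation {rel!r}; expected one of {RELATIONS}")
    return _RULE_TABLE.get((rel_fm, rel_hf, rel_hm), UNCLASSIFIED)


def category_of(cls) -> str:
    """Category label for a class index (deterministic lookup)."""
    try:
        return CLASS_CATEGORY[cls]
    except KeyError:
        raise ValueError(f"unknown class label {cls!r}") from None


def relations_from_means(mu_f: float, mu_m: float, mu_h: float) -> Tuple[str, str, str]:
    """Exact relations of a noise-free mean triple (truth-table use)."""

    def rel(a: float, b: float) -> str:
        if a > b:
            return ">"
        if a < b:
            return "<"
        return "="

    return rel(mu_f, mu_m), rel(mu_h, mu_f), rel(mu_h, mu_m)


def calls_to_relations(
    call_fm: str, call_hf: str, call_hm: str
) -> Tuple[str, str, str]:
    """Convert three-valued DE calls to relation symbols.

    The DE engine reports a call for a comparison named ``"A vs B"`` with
    ``up`` meaning B higher.  For the triad the three comparisons are
    "F vs M", "F vs H" and "M vs H", so ``up`` in "F vs M" means the male
    parent is higher, and ``up`` in the hybrid comparisons means the
    hybrid is higher.
    """
    flip = {"up": "<", "down": ">", "ns": "="}      # F vs M: up = M higher = F<M
    hyb = {"up": ">", "down": "<", "ns": "="}       # parent vs H: up = H higher
    try:
        return flip[call_fm], hyb[call_hf], hyb[call_hm]
    except KeyError as exc:
        raise ValueError(f"invalid call {exc.args[0]!r}; expected up/down/ns") from None


def classify_triad(
    calls: pd.DataFrame, universe: Optional[Sequence] = None
) -> pd.DataFrame:
    """Classify every gene of a triad from its three pairwise DE calls.

    Parameters
    ----------
    calls
        DataFrame indexed by gene id with columns ``call_FM`` (female vs
        male), ``call_HF`` (hybrid vs female) and ``call_HM`` (hybrid vs
        male), each in ``{"up", "down", "ns"}``.
    universe
        Optional collection of gene ids forming the classified universe
        (typically the genes that are DEGs in at least one of the three
        comparisons).  Genes outside it are reported as conserved.  When
        omitted, every gene with at least one non-ns call is classified.

    Returns
    -------
    DataFrame
        Indexed by gene id with columns ``class`` (str: "1".."12",
        "conserved" or "unclassified") and ``category``.
    """
    required = {"call_FM", "call_HF", "call_HM"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")
    in_universe = None if universe is None else set(universe)

    labels = []
    for gene, row in calls.iterrows():
        if in_universe is not None and gene not in in_universe:
            cls: object = CONSERVED
        else:
            rels = calls_to_relations(row["call_FM"], row["call_HF"], row["call_HM"])
            cls = classify_gene(*rels)
        labels.append((gene, str(cls), category_of(cls)))
    out = pd.DataFrame(labels, columns=["gene_id", "class", "category"])
    return out.set_index("gene_id")


def summarize_patterns(assignment: pd.DataFrame) -> Tuple[pd.Series, pd.Series]:
    """Per-class and per-category gene counts of a pattern assignment.

    Conserved genes are excluded from class counts (they are outside the
    DEG universe) but appear in the category summary.
    """
    class_order = [str(i) for i in range(1, 13)] + [UNCLASSIFIED]
    in_universe = assignment[assignment["class"] != CONSERVED]
    class_counts = (
        in_universe["class"].value_counts().reindex(class_order, fill_value=0)
    )
    cat_order = list(CATEGORIES) + [CONSERVED, UNCLASSIFIED]
    cat_counts = (
        assignment["category"].value_counts().reindex(cat_order, fill_value=0)
    )
    return class_counts, cat_counts


def swap_parents(assignment: pd.DataFrame) -> pd.DataFrame:
    """Relabel an assignment as if female and male parents were exchanged.

    Classes map 1<->2, 3<->5, 4<->6, 8<->9, 11<->12; classes 7 and 10
    (parents-equal overdominance), conserved and unclassified are fixed.
    Applying the map twice is the identity.
    """
    def _swap(label: str) -> str:
        key: object = int(label) if label.isdigit() else label
        return str(SWAP_MAP[key])

    out = assignment.copy()
    out["class"] = out["class"].map(_swap)
    out["category"] = out["class"].map(
        lambda c: category_of(int(c) if c.isdigit() else c)
    )
    return out


def intersect_deg_sets(named_sets: Mapping[str, Iterable[str]]) -> Dict[str, int]:
    """Venn-region counts for two or three named gene sets.

    Returns a dict mapping each exclusive region (keyed by the
    ``"&"``-joined sorted member names) to its gene count, plus
    ``"common"`` for the full intersection.
    """
    sets = {name: set(s) for name, s in named_sets.items()}
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("intersect_deg_sets supports 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: Dict[frozenset, int] = {}
    for gene in universe:
        member = frozenset(n for n in names if gene in sets[n])
        regions[member] = regions.get(member, 0) + 1
    out: Dict[str, int] = {}
    # every non-empty membership combination, zero-filled
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            out["&".join(sorted(combo))] = regions.get(frozenset(combo), 0)
    out["common"] = regions.get(frozenset(names), 0)
    return out
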