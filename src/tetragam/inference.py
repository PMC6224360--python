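"""Infer diploid gametes from triploid progeny and evaluate null-allele scenarios.

The study design crosses a diploid seed parent with a tetraploid somatic
hybrid, so each triploid progeny genotype is one maternal allele plus the
intact diploid pollen gamete.  Because the seed parent is genetically
differentiated from the tetraploid parent, the gamete is recovered by
subtracting the maternal contribution from the dosage-annotated triploid
call.

Null (non-amplifying) alleles complicate this: a gamete carrying a null shows
a visible dosage of one, and parental constitutions that differ only in null
content (e.g. ``abc0`` vs ``abcc``) predict different identities for such
gametes.  :func:`null_allele_scenario_test` ranks candidate constitutions by
a goodness-of-fit G statistic computed at the fitted segregation model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model import (
    NULL_ALLELE,
    Allele,
    GameteClass,
    TetraploidGenotype,
    gamete_class,
)

__all__ = [
    "MaternalGenotype",
    "TriploidCall",
    "GameteCall",
    "LocusCounts",
    "InferenceError",
    "infer_gamete",
    "tabulate_gametes",
    "visible_signature",
    "signature_counts",
    "complete_signature",
    "standard_null_candidates",
    "null_allele_scenario_test",
    "validate_maternal",
]


class InferenceError(ValueError):
    """Raised when a triploid call cannot be resolved into a gamete."""


@dataclass(frozen=True)
class MaternalGenotype:
    """Diploid seed-parent genotype at one locus (two allele symbols)."""

    locus_name: str
    alleles: Tuple[Allele, Allele]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("maternal genotype carries exactly two alleles")

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]


@dataclass(frozen=True)
class TriploidCall:
    """Observed triploid progeny genotype with allele dosage.

    ``dosages`` maps each visible allele to its copy number.  The visible
    total is 3 for a fully amplifying locus; gametes carrying null alleles
    reduce it (to 2 for one null, 1 for a double-null gamete).
    """

    progeny_id: str
    locus_name: str
    dosages: Mapping[Allele, int]
    missing: bool = False

    @property
    def total_dosage(self) -> int:
        return sum(self.dosages.values())


@dataclass(frozen=True)
class GameteCall:
    """An inferred (or simulated) diploid gamete for one progeny and locus.

    ``status`` is ``"ok"`` for a resolved gamete; excluded records carry the
    reason (``"missing"``, ``"no_maternal_allele"``, ``"ambiguous"``).
    """

    progeny_id: str
    locus_name: str
    gamete: Optional[GameteClass]
    provenance: str = "inferred"
    status: str = "ok"


@dataclass
class LocusCounts:
    """Observed gamete-class counts at one locus.

    Keys are canonical gamete classes (sorted allele pairs); for merged,
    dosage-free data they may be visible-allele signatures instead, which is
    why the key type is left open.
    """

    locus_name: str
    counts: Dict[Hashable, int]

    def __post_init__(self) -> None:
        for cls, k in self.counts.items():
            if k < 0:
                raise ValueError(f"negative count for class {cls!r}")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def observed_alleles(self) -> Tuple[Allele, ...]:
        alleles = set()
        for cls in self.counts:
            alleles.update(cls)
        return tuple(sorted(alleles))


def validate_maternal(
    maternal: MaternalGenotype, paternal: TetraploidGenotype
) -> None:
    """Fail fast on configurations where maternal subtraction is ambiguous.

    A heterozygous maternal genotype sharing alleles with the tetraploid
    parent can make the subtraction non-unique; such loci are rejected at
    configuration load.  A *homozygous* maternal genotype may share its
    allele (the centromeric SNP design: AA mother x AABB father), because
    only one distinct allele is ever removable.
    """
    overlap = set(maternal.alleles) & set(paternal.alleles)
    if overlap and not maternal.is_homozygous:
        raise ValueError(
            f"locus {maternal.locus_name}: heterozygous maternal genotype shares "
            f"alleles {sorted(overlap)} with the tetraploid parent; gamete "
            "inference would be ambiguous"
        )


def infer_gamete(
    call: TriploidCall,
    maternal: MaternalGenotype,
    n_null_alleles: int = 0,
) -> GameteCall:
    """Subtract the maternal contribution from a triploid call.

    Removes exactly one copy of exactly one maternal allele; the remaining
    dosage-2 multiset is the gamete.  ``n_null_alleles`` is the number of
    null alleles in the active paternal constitution: each null in the gamete
    lowers the visible dosage by one, and the shortfall is restored as
    ``"0"`` symbols.  A progeny showing only a single maternal allele is
    classed as a double-null gamete iff a two-null constitution is active.
    """
    if call.missing:
        return GameteCall(call.progeny_id, call.locus_name, None, status="missing")
    total = call.total_dosage
    if any(d <= 0 for d in call.dosages.values()):
        raise InferenceError(
            f"{call.progeny_id}/{call.locus_name}: non-positive allele dosage"
        )
    if not 3 - n_null_alleles <= total <= 3:
        raise InferenceError(
            f"{call.progeny_id}/{call.locus_name}: visible dosage {total} "
            f"incompatible with ploidy 3 and {n_null_alleles} null allele(s)"
        )

    removable = [a for a in set(maternal.alleles) if call.dosages.get(a, 0) >= 1]
    if not removable:
        return GameteCall(
            call.progeny_id, call.locus_name, None, status="no_maternal_allele"
        )
    gametes = set()
    for a in removable:
        rest: Counter = Counter(call.dosages)
        rest[a] -= 1
        alleles = sorted(rest.elements())
        alleles.extend([NULL_ALLELE] * (2 - len(alleles)))
        gametes.add(gamete_class(alleles[0], alleles[1]))
    if len(gametes) > 1:
        return GameteCall(call.progeny_id, call.locus_name, None, status="ambiguous")
    return GameteCall(call.progeny_id, call.locus_name, gametes.pop())


def tabulate_gametes(calls: Iterable[GameteCall]) -> Dict[str, LocusCounts]:
    """Per-locus gamete-class counts; non-``ok`` records are excluded from n."""
    counts: Dict[str, Dict[Hashable, int]] = {}
    for call in calls:
        per_locus = counts.setdefault(call.locus_name, {})
        if call.status != "ok" or call.gamete is None:
            continue
        per_locus[call.gamete] = per_locus.get(call.gamete, 0) + 1
    return {locus: LocusCounts(locus, c) for locus, c in counts.items()}


# ---------------------------------------------------------------------------
# Null-allele constitution evaluation
# ---------------------------------------------------------------------------

def visible_signature(cls: GameteClass) -> Tuple[Allele, ...]:
    """What a gamete class looks like without dosage information.

    The distinct non-null alleles: without dosage, ``AA`` and ``A0`` are both
    seen as a lone ``A`` and share the signature ``('A',)``.
    """
    return tuple(sorted({a for a in cls if a != NULL_ALLELE}))


def signature_counts(counts: LocusCounts) -> Dict[Tuple[Allele, ...], int]:
    """Collapse gamete-class counts to visible-allele signatures."""
    out: Dict[Tuple[Allele, ...], int] = {}
    for cls, k in counts.counts.items():
        sig = visible_signature(tuple(cls))
        out[sig] = out.get(sig, 0) + k
    return out


def complete_signature(
    sig: Tuple[Allele, ...], constitution: TetraploidGenotype
) -> GameteClass:
    """Map a visible signature back to a gamete class under a constitution.

    A two-allele signature is already a class.  A single visible allele is
    completed with the null symbol when the constitution carries nulls
    (``A`` -> ``A0``) and doubled otherwise (``A`` -> ``AA``); an empty
    signature is the double-null gamete.
    """
    has_null = NULL_ALLELE in constitution.alleles
    if len(sig) == 2:
        return gamete_class(sig[0], sig[1])
    if len(sig) == 1:
        partner = NULL_ALLELE if has_null else sig[0]
        return gamete_class(sig[0], partner)
    return gamete_class(NULL_ALLELE, NULL_ALLELE)


def standard_null_candidates(
    genotype: TetraploidGenotype,
) -> List[TetraploidGenotype]:
    """Candidate parental constitutions for a locus with < 4 distinct alleles.

    For three visible alleles with parents ``ab`` and ``cc`` the candidates
    are ``abcc`` and ``abc0``; for two visible alleles with parents ``aa``
    and ``bb`` they are ``aabb``, ``aab0``, ``abb0`` and ``ab00``.  More
    generally, every constitution obtained by replacing duplicated copies of
    an allele with nulls (within each genome independently) is generated.
    """
    from itertools import product

    per_genome: Dict[str, List[Tuple[Allele, Allele]]] = {}
    for genome in ("M", "P"):
        a, b = genotype.alleles_of(genome)
        options = [(a, b)]
        if a == b and a != NULL_ALLELE:
            options.append((a, NULL_ALLELE))
            options.append((NULL_ALLELE, NULL_ALLELE))
        elif a == NULL_ALLELE and b != NULL_ALLELE:
            options.append((b, b))  # the stated null may instead be a duplicate
        elif b == NULL_ALLELE and a != NULL_ALLELE:
            options.append((a, a))
        per_genome[genome] = options
    candidates = []
    for m_opt, p_opt in product(per_genome["M"], per_genome["P"]):
        if set(m_opt) == {NULL_ALLELE} and set(p_opt) == {NULL_ALLELE}:
            continue  # no visible paternal allele at all
        candidates.append(
            TetraploidGenotype.from_parents(
                genotype.locus_name, m_opt, p_opt, genotype.linkage_group
            )
        )
    return candidates


def null_allele_scenario_test(
    counts: LocusCounts,
    candidates: Sequence[TetraploidGenotype],
    **fit_options,
):
    """Rank candidate parental constitutions by goodness of fit.

    The observed counts are collapsed to visible-allele signatures (dosage
    information cannot distinguish e.g. ``A0`` from ``AA`` without knowing
    the constitution).  For each candidate the segregation mixture model is
    fitted on the signature-merged classes and the deviance
    ``G = 2 sum O ln(O/E)`` evaluated at the fitted expectation; candidates
    are returned sorted by ascending G.

    Returns a list of ``(candidate, G, FitResult)`` tuples.
    """
    from .fit import fit_locus  # deferred: fit depends on LocusCounts

    if not candidates:
        raise ValueError("candidate list is empty")
    observed = signature_counts(counts)
    observed_alleles = {a for sig in observed for a in sig}
    ranked = []
    for cand in candidates:
        visible = {a for a in cand.alleles if a != NULL_ALLELE}
        if not observed_alleles <= visible:
            raise ValueError(
                f"candidate {cand.alleles} for {counts.locus_name} does not cover "
                f"observed alleles {sorted(observed_alleles)}"
            )
        merged = LocusCounts(counts.locus_name, dict(observed))
        fit = fit_locus(merged, cand, merge=visible_signature, **fit_options)
        ranked.append((cand, fit.deviance_G, fit))
    ranked.sort(key=lambda item: item[1])
    return ranked
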