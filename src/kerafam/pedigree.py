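"""Pedigrees with affection status and linkage-haplotype labels.

A pedigree is read from a whitespace-delimited PED file with the classic six
columns (family, individual, father, mother, sex, affection) plus two optional
extension columns:

==========  =============================================================
column 7    linkage-haplotype label: ``L`` (linked with disease),
            ``U`` (unlinked), ``?`` (unknown)
column 8    sequencing set: ``WES``, ``WGS``, ``BOTH``, ``NONE``
==========  =============================================================

Affection coding follows the standard PED dialect: 2 = affected,
1 = unaffected, 0 or -9 = unknown.  Missing parents are coded ``0``.
Individual ids are opaque strings; roman-numeral generation labels are an
optional side mapping, never inferred from the ids.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping


class PedigreeError(ValueError):
    """Structural problem in a pedigree or PED file."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Haplotype(str, enum.Enum):
    LINKED = "linked"
    UNLINKED = "unlinked"
    UNKNOWN = "unknown"


class SeqSet(str, enum.Enum):
    WES = "wes"
    WGS = "wgs"
    BOTH = "both"
    NONE = "none"


_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_AFF_TO_PED = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}
_HAP_FROM_PED = {"L": Haplotype.LINKED, "U": Haplotype.UNLINKED, "?": Haplotype.UNKNOWN}
_HAP_TO_PED = {v: k for k, v in _HAP_FROM_PED.items()}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders; when present they
    must resolve to individuals of the same family.
    """

    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    haplotype: Haplotype = Haplotype.UNKNOWN
    sequenced: SeqSet = SeqSet.NONE

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """An ordered collection of :class:`Individual` with resolved parent links.

    Validates on construction that parent references resolve within the same
    family, that every non-founder has exactly two parents, and that the
    parentage graph is acyclic.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        generation_labels: Mapping[str, str] | None = None,
    ) -> None:
        self._individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self._individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        self.generation_labels = dict(generation_labels or {})
        self._validate()

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self._individuals)

    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise PedigreeError(f"unknown individual id {individual_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self._individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self._individuals if ind.is_founder]

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for ind in self._individuals:
            n_parents = sum(p is not None for p in (ind.father_id, ind.mother_id))
            if n_parents == 1:
                raise PedigreeError(
                    f"individual {ind.id!r} has exactly one parent; "
                    "non-founders need both, founders neither"
                )
            for parent_id in (ind.father_id, ind.mother_id):
                if parent_id is None:
                    continue
                if parent_id not in self._by_id:
                    raise PedigreeError(
                        f"individual {ind.id!r} names parent {parent_id!r} "
                        "not present in the pedigree"
                    )
                parent = self._by_id[parent_id]
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"individual {ind.id!r} names parent {parent_id!r} "
                        "from a different family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._by_id}
        for start in self._by_id:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if color[node] == GRAY:
                        raise PedigreeError(f"cyclic parentage involving {node!r}")
                    if color[node] == BLACK:
                        continue
                    color[node] = GRAY
                    stack.append((node, 1))
                    ind = self._by_id[node]
                    for parent_id in (ind.father_id, ind.mother_id):
                        if parent_id is not None and color[parent_id] != BLACK:
                            if color[parent_id] == GRAY:
                                raise PedigreeError(
                                    f"cyclic parentage involving {parent_id!r}"
                                )
                            stack.append((parent_id, 0))
                else:
                    color[node] = BLACK

    # -- queries ------------------------------------------------------------
    def topological_order(self) -> list[Individual]:
        """Individuals ordered so every parent precedes its children."""
        order: list[Individual] = []
        done: set[str] = set()
        pending = list(self._individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
                if all(p in done for p in parents):
                    order.append(ind)
                    done.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            pending = remaining
            if pending and not progressed:  # pragma: no cover - guarded by _check_acyclic
                raise PedigreeError("cyclic parentage")
        return order

    def haplotype_carriers(self) -> frozenset[str]:
        """Ids of individuals labeled as carrying the disease-linked haplotype."""
        return frozenset(
            ind.id for ind in self._individuals if ind.haplotype is Haplotype.LINKED
        )

    def selected(self, mode: SeqSet | str) -> list[str]:
        """Sample ids in the WES or WGS analysis set (``both`` counts for either)."""
        mode = SeqSet(mode)
        if mode not in (SeqSet.WES, SeqSet.WGS):
            raise PedigreeError(f"selection mode must be wes or wgs, got {mode}")
        return [
            ind.id
            for ind in self._individuals
            if ind.sequenced is mode or ind.sequenced is SeqSet.BOTH
        ]

    def with_statuses(
        self,
        affected: Mapping[str, Affection] | None = None,
        haplotype: Mapping[str, Haplotype] | None = None,
    ) -> "Pedigree":
        """A copy with affection and/or haplotype labels replaced."""
        new = []
        for ind in self._individuals:
            kwargs = {}
            if affected is not None and ind.id in affected:
                kwargs["affected"] = affected[ind.id]
            if haplotype is not None and ind.id in haplotype:
                kwargs["haplotype"] = haplotype[ind.id]
            new.append(replace(ind, **kwargs) if kwargs else ind)
        return Pedigree(new, self.generation_labels)

    # -- I/O ----------------------------------------------------------------
    def write_ped(self) -> str:
        """Render as PED text with the two extension columns."""
        out = io.StringIO()
        for ind in self._individuals:
            fields = [
                ind.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_TO_PED[ind.sex],
                _AFF_TO_PED[ind.affected],
                _HAP_TO_PED[ind.haplotype],
                ind.sequenced.value.upper(),
            ]
            out.write("\t".join(fields) + "\n")
        return out.getvalue()


def parse_ped(text: str | io.TextIOBase) -> Pedigree:
    """Parse PED text (6 columns, optional haplotype and sequencing columns).

    Raises :class:`PedigreeError` naming the offending row for malformed
    rows, dangling parent references, and cyclic parentage.
    """
    if hasattr(text, "read"):
        text = text.read()
    individuals: list[Individual] = []
    for lineno, raw in enumerate(str(text).splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"row {lineno}: expected at least 6 columns, got {len(fields)}"
            )
        fam, iid, father, mother, sex_code, aff_code = fields[:6]
        hap_code = fields[6] if len(fields) > 6 else "?"
        seq_code = fields[7] if len(fields) > 7 else "NONE"
        try:
            sex = _SEX_FROM_PED[sex_code]
        except KeyError:
            raise PedigreeError(f"row {lineno}: bad sex code {sex_code!r}") from None
        try:
            affected = _AFF_FROM_PED[aff_code]
        except KeyError:
            raise PedigreeError(
                f"row {lineno}: bad affection code {aff_code!r}"
            ) from None
        try:
            haplotype = _HAP_FROM_PED[hap_code.upper()]
        except KeyError:
            raise PedigreeError(
                f"row {lineno}: bad haplotype code {hap_code!r}"
            ) from None
        try:
            sequenced = SeqSet(seq_code.lower())
        except ValueError:
            raise PedigreeError(
                f"row {lineno}: bad sequencing-set code {seq_code!r}"
            ) from None
        individuals.append(
            Individual(
                id=iid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex,
                affected=affected,
                haplotype=haplotype,
                sequenced=sequenced,
            )
        )
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        # Attach row context for dangling references.
        msg = str(exc)
        for lineno, raw in enumerate(str(text).splitlines(), start=1):
            fields = raw.split()
            if len(fields) >= 6 and f"{fields[1]!r}" in msg:
                raise PedigreeError(f"row {lineno}: {msg}") from None
        raise


Genotype = tuple[int, int]


def mendelian_violations(
    pedigree: Pedigree, genotypes: Mapping[str, Genotype | None]
) -> list[tuple[str, str]]:
    """Individuals whose biallelic genotype is impossible given their parents.

    ``genotypes`` maps individual id to an allele-index pair (or ``None`` for
    a missing call) at one biallelic site.  An empty result means the site is
    Mendelian-consistent.  Checks are skipped where the child or both parents
    are uncalled; with one called parent the child must be able to draw one
    allele from that parent.
    """
    for sample_id in genotypes:
        if sample_id not in pedigree:
            raise PedigreeError(f"genotype given for unknown individual {sample_id!r}")

    violations: list[tuple[str, str]] = []
    for ind in pedigree:
        child = genotypes.get(ind.id)
        if child is None or ind.is_founder:
            continue
        father = genotypes.get(ind.father_id) if ind.father_id else None
        mother = genotypes.get(ind.mother_id) if ind.mother_id else None
        if father is None and mother is None:
            continue
        a, b = child
        if father is not None and mother is not None:
            ok = any(
                x in father and y in mother for x, y in ((a, b), (b, a))
            )
            reason = (
                f"genotype {child} impossible from father {father} "
                f"and mother {mother}"
            )
        else:
            parent = father if father is not None else mother
            ok = a in parent or b in parent
            reason = f"genotype {child} shares no allele with called parent {parent}"
        if not ok:
            violations.append((ind.id, reason))
    return violations
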