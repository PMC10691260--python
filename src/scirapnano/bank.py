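"""Versioned criteria banks for reliability and relevance evaluation.

A *criteria bank* holds the full checklist an evaluator works through for one
study: reporting-quality (RQ) criteria, methodological-quality (MQ) criteria
and relevance (REL) items, together with two registries that connect the
criteria back to the physicochemical parameters and nanomaterial-specific
aspects they were derived from.

Two banks ship with the package:

``"2.0"``
    The full SciRAPnano in vitro tool: 38 RQ criteria, 19 MQ criteria and
    4 relevance items, with verbatim criterion wording, provenance flags
    (which criteria are new for nanomaterials, reworded, or replaced), the
    11 key physicochemical parameters, the 8 nanomaterial-specific aspects
    of in vitro testing, and the 4 low-priority properties folded into the
    open "other information" criterion.

``"1.0-skeleton"``
    Ids and section labels of tool version 1.0 (33 RQ, 19 MQ, 4 REL), the
    version the packaged titanium-dioxide case study was rated against.
    The 1.0 wordings are not distributed; entries carry a text-unavailable
    marker.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import yaml

__all__ = [
    "Part",
    "RatingScale",
    "Criterion",
    "KeyParameter",
    "AspectEntry",
    "CriteriaBank",
    "Violation",
    "BUILTIN_VERSIONS",
    "UnsupportedBankVersionError",
    "BankFileError",
    "load_builtin_bank",
    "validate_bank",
    "select_criteria",
    "registry_counts",
    "read_bank",
    "write_bank",
    "normalize_text",
]

BUILTIN_VERSIONS = ("2.0", "1.0-skeleton")

#: Closed vocabulary of provenance flags a criterion may carry.
PROVENANCE_FLAGS = frozenset({"new_nm_specific", "reworded", "replaced_original", "unchanged"})

#: Closed vocabulary of applicability predicates.
APPLICABILITY_CONDITIONS = frozenset({"cell_line_only"})

#: Placeholder wording stored when a bank version's texts are not distributed.
TEXT_UNAVAILABLE = "[criterion text not available in this bank version]"

_WS = re.compile(r"\s+")
_QUOTES = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'"})


def normalize_text(text: str) -> str:
    """Normalize criterion wording: straight quotes, single internal spaces."""
    return _WS.sub(" ", text.translate(_QUOTES)).strip()


class Part(str, Enum):
    """The three sections of the tool: reporting quality, methodological quality, relevance."""

    RQ = "RQ"
    MQ = "MQ"
    REL = "REL"


class RatingScale(str, Enum):
    QUALITY = "quality"        # F / PF / NF / ND
    RELEVANCE = "relevance"    # DR / IR / NR / ND


class UnsupportedBankVersionError(ValueError):
    """Raised when a built-in bank version is requested that does not exist."""


class BankFileError(ValueError):
    """Raised when a bank file cannot be parsed or fails schema checks."""


@dataclass(frozen=True)
class Criterion:
    """One evaluation criterion or relevance item.

    ``provenance`` records how the criterion relates to the original
    (non-nano) in vitro tool; ``tags`` are registry keys tying the criterion
    to the parameter/aspect registries; ``applicability_condition`` names a
    study-metadata predicate under which the criterion applies (e.g.
    ``cell_line_only`` — removed from evaluations of studies not conducted
    in a cell line); ``open_ended`` marks the free-form "other information"
    criteria.
    """

    id: int
    part: Part
    section: str
    text: str
    guidance: str | None = None
    rating_scale: RatingScale = RatingScale.QUALITY
    provenance: frozenset = frozenset({"unchanged"})
    applicability_condition: str | None = None
    open_ended: bool = False
    tags: tuple = ()
    text_available: bool = True

    @property
    def key(self) -> tuple[Part, int]:
        return (self.part, self.id)

    def label(self) -> str:
        return f"{self.part.value}{self.id}"


@dataclass(frozen=True)
class KeyParameter:
    """A key physicochemical parameter and the criteria that report it."""

    name: str
    mapped_criterion_ids: tuple
    note: str | None = None


@dataclass(frozen=True)
class AspectEntry:
    """A nanomaterial-specific aspect or low-priority property and its criteria."""

    name: str
    mapped_criterion_ids: tuple
    registry: str  # "nm_aspect" | "low_priority_property"


@dataclass(frozen=True)
class CriteriaBank:
    """Versioned, ordered container of criteria plus parameter/aspect registries."""

    tool_name: str
    version: str
    criteria: Mapping  # Part -> tuple[Criterion, ...]
    key_parameters: tuple = ()
    aspects: tuple = ()

    def part(self, part: Part | str) -> tuple:
        return tuple(self.criteria.get(Part(part), ()))

    def get(self, part: Part | str, cid: int) -> Criterion:
        for c in self.part(part):
            if c.id == cid:
                return c
        raise KeyError(f"no criterion {Part(part).value}{cid} in bank {self.version!r}")

    def has(self, part: Part | str, cid: int) -> bool:
        return any(c.id == cid for c in self.part(part))

    def all_criteria(self) -> tuple:
        return tuple(c for p in Part for c in self.part(p))

    def sections(self, part: Part | str) -> tuple:
        """Section labels of a part in criterion order, deduplicated."""
        seen: list[str] = []
        for c in self.part(part):
            if c.section not in seen:
                seen.append(c.section)
        return tuple(seen)


@dataclass(frozen=True)
class Violation:
    """One broken bank invariant: which part/id, which rule, and a message."""

    part: str | None
    criterion_id: int | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.part}{self.criterion_id}" if self.part else "bank"
        return f"[{self.rule}] {where}: {self.message}"


# --- expected shape of the built-in banks, used by validate_bank -------------

_EXPECTED_IDS = {
    "2.0": {Part.RQ: 38, Part.MQ: 19, Part.REL: 4},
    "1.0-skeleton": {Part.RQ: 33, Part.MQ: 19, Part.REL: 4},
}

_EXPECTED_RQ_SECTIONS = {
    "2.0": ((1, 4), (5, 16), (17, 24), (25, 29), (30, 35), (36, 37), (38, 38)),
    "1.0-skeleton": ((1, 4), (5, 15), (16, 22), (23, 26), (27, 31), (32, 33)),
}

_EXPECTED_REGISTRY_COUNTS = {"2.0": {"key_parameters": 11, "nm_aspect": 8, "low_priority_property": 4}}


def _registry_names(bank: CriteriaBank) -> set[str]:
    names = {p.name for p in bank.key_parameters}
    names.update(a.name for a in bank.aspects)
    return names


def validate_bank(bank: CriteriaBank) -> list[Violation]:
    """Check every bank invariant; return violations as data (never raises).

    An empty list means the bank is internally consistent: unique contiguous
    ids per part, non-empty wording, rating scales matching parts, known
    provenance flags / tags / applicability conditions, registries resolving
    to existing criteria, and — for the built-in versions — the expected id
    ranges, section partitions and registry cardinalities.
    """
    out: list[Violation] = []

    for part in Part:
        crits = bank.part(part)
        seen_ids: set[int] = set()
        for c in crits:
            if c.part is not part:
                out.append(Violation(part.value, c.id, "part-mismatch",
                                     f"criterion stored under {part.value} has part={c.part.value}"))
            if c.id in seen_ids:
                out.append(Violation(part.value, c.id, "duplicate-id", "id occurs more than once in part"))
            seen_ids.add(c.id)
            if not isinstance(c.id, int) or c.id < 1:
                out.append(Violation(part.value, c.id, "bad-id", "id must be a positive integer"))
            if not normalize_text(c.text):
                out.append(Violation(part.value, c.id, "empty-text", "criterion text is empty"))
            expected_scale = RatingScale.RELEVANCE if part is Part.REL else RatingScale.QUALITY
            if c.rating_scale is not expected_scale:
                out.append(Violation(part.value, c.id, "scale-mismatch",
                                     f"{part.value} criterion must use the {expected_scale.value} scale"))
            unknown_flags = set(c.provenance) - PROVENANCE_FLAGS
            if unknown_flags:
                out.append(Violation(part.value, c.id, "unknown-flag",
                                     f"unknown provenance flag(s): {sorted(unknown_flags)}"))
            if c.applicability_condition is not None and c.applicability_condition not in APPLICABILITY_CONDITIONS:
                out.append(Violation(part.value, c.id, "unknown-condition",
                                     f"unknown applicability condition {c.applicability_condition!r}"))
            for tag in c.tags:
                if tag not in _registry_names(bank):
                    out.append(Violation(part.value, c.id, "unknown-tag",
                                         f"tag {tag!r} is not a registry key"))

        expected_n = _EXPECTED_IDS.get(bank.version, {}).get(part)
        if expected_n is not None and {c.id for c in crits} != set(range(1, expected_n + 1)):
            out.append(Violation(part.value, None, "id-range",
                                 f"{part.value} ids must be exactly 1..{expected_n} for version {bank.version}"))

    # section partition of RQ for the built-in versions
    expected_sections = _EXPECTED_RQ_SECTIONS.get(bank.version)
    if expected_sections is not None:
        crits = sorted(bank.part(Part.RQ), key=lambda c: c.id)
        blocks: list[tuple[int, int]] = []
        for c in crits:
            if blocks and c.section == section_of_last:
                blocks[-1] = (blocks[-1][0], c.id)
            else:
                blocks.append((c.id, c.id))
            section_of_last = c.section
        if tuple(blocks) != expected_sections:
            out.append(Violation(Part.RQ.value, None, "section-partition",
                                 f"RQ section blocks {blocks} != expected {list(expected_sections)}"))

    # registries resolve and names are unique
    names: set[str] = set()
    for entry in (*bank.key_parameters, *bank.aspects):
        if entry.name in names:
            out.append(Violation(None, None, "duplicate-registry-name", f"registry name {entry.name!r} repeated"))
        names.add(entry.name)
        for part, cid in entry.mapped_criterion_ids:
            if not bank.has(part, cid):
                out.append(Violation(None, None, "dangling-registry-ref",
                                     f"registry entry {entry.name!r} maps to missing {Part(part).value}{cid}"))

    expected_reg = _EXPECTED_REGISTRY_COUNTS.get(bank.version)
    if expected_reg is not None:
        got = registry_counts(bank)
        for key, n in expected_reg.items():
            if got.get(key, 0) != n:
                out.append(Violation(None, None, "registry-count",
                                     f"{key} has {got.get(key, 0)} entries, expected {n}"))
    # low-priority properties must all map to an open-ended criterion
    for a in bank.aspects:
        if a.registry == "low_priority_property":
            for part, cid in a.mapped_criterion_ids:
                if bank.has(part, cid) and not bank.get(part, cid).open_ended:
                    out.append(Violation(Part(part).value, cid, "low-priority-mapping",
                                         f"low-priority property {a.name!r} must map to the open criterion"))
    return out


_FILTER_FIELDS = {"part", "section", "flag", "tag", "open_ended", "applicability_condition"}


def select_criteria(
    bank: CriteriaBank,
    where: Callable[[Criterion], bool] | None = None,
    **filters,
) -> list[Criterion]:
    """Order-preserving subset of the bank's criteria.

    Keyword filters: ``part``, ``section``, ``flag`` (provenance flag),
    ``tag`` (registry key), ``open_ended``, ``applicability_condition``.
    ``where`` is an arbitrary extra predicate. Unknown filter names raise
    ``ValueError``.
    """
    unknown = set(filters) - _FILTER_FIELDS
    if unknown:
        raise ValueError(f"unknown filter field(s): {sorted(unknown)}; known: {sorted(_FILTER_FIELDS)}")

    def keep(c: Criterion) -> bool:
        if "part" in filters and c.part is not Part(filters["part"]):
            return False
        if "section" in filters and c.section != filters["section"]:
            return False
        if "flag" in filters and filters["flag"] not in c.provenance:
            return False
        if "tag" in filters and filters["tag"] not in c.tags:
            return False
        if "open_ended" in filters and c.open_ended != bool(filters["open_ended"]):
            return False
        if "applicability_condition" in filters and c.applicability_condition != filters["applicability_condition"]:
            return False
        return where(c) if where is not None else True

    return [c for c in bank.all_criteria() if keep(c)]


def registry_counts(bank: CriteriaBank) -> dict[str, int]:
    """Entry counts of the three registries."""
    return {
        "key_parameters": len(bank.key_parameters),
        "nm_aspect": sum(1 for a in bank.aspects if a.registry == "nm_aspect"),
        "low_priority_property": sum(1 for a in bank.aspects if a.registry == "low_priority_property"),
    }


# --- (de)serialization -------------------------------------------------------

def _parse_ref(ref: str, where: str) -> tuple[Part, int]:
    m = re.fullmatch(r"(RQ|MQ|REL)(\d+)", str(ref).strip())
    if not m:
        raise BankFileError(f"{where}: bad criterion reference {ref!r} (expected e.g. 'RQ5')")
    return Part(m.group(1)), int(m.group(2))


def _criterion_from_dict(part: Part, d: Mapping, where: str) -> Criterion:
    if not isinstance(d, Mapping) or "id" not in d:
        raise BankFileError(f"{where}: each criterion needs at least an 'id' field")
    known = {"id", "section", "text", "guidance", "rating_scale", "provenance",
             "applicability_condition", "open_ended", "tags", "text_available"}
    extra = set(d) - known
    if extra:
        raise BankFileError(f"{where}: unknown criterion field(s) {sorted(extra)}")
    text_available = bool(d.get("text_available", True))
    text = d.get("text")
    if text is None:
        if text_available:
            raise BankFileError(f"{where}: missing 'text' (set text_available: false to omit)")
        text = TEXT_UNAVAILABLE
    scale = RatingScale(d.get("rating_scale",
                              RatingScale.RELEVANCE.value if part is Part.REL else RatingScale.QUALITY.value))
    return Criterion(
        id=int(d["id"]),
        part=part,
        section=normalize_text(str(d.get("section", ""))),
        text=normalize_text(str(text)),
        guidance=normalize_text(str(d["guidance"])) if d.get("guidance") else None,
        rating_scale=scale,
        provenance=frozenset(d.get("provenance", ["unchanged"])),
        applicability_condition=d.get("applicability_condition"),
        open_ended=bool(d.get("open_ended", False)),
        tags=tuple(d.get("tags", ())),
        text_available=text_available,
    )


def _bank_from_dict(data: Mapping, source: str) -> CriteriaBank:
    if not isinstance(data, Mapping):
        raise BankFileError(f"{source}: top level must be a mapping")
    for req in ("tool_name", "version", "criteria"):
        if req not in data:
            raise BankFileError(f"{source}: missing required top-level field {req!r}")
    criteria: dict[Part, tuple] = {}
    for part in Part:
        entries = (data["criteria"] or {}).get(part.value, [])
        criteria[part] = tuple(
            _criterion_from_dict(part, e, f"{source}: criteria.{part.value}[{i}]")
            for i, e in enumerate(entries)
        )
    registries = data.get("registries") or {}
    key_params = tuple(
        KeyParameter(
            name=str(e["name"]),
            mapped_criterion_ids=tuple(_parse_ref(r, f"{source}: key_parameters[{i}]") for r in e.get("criteria", [])),
            note=e.get("note"),
        )
        for i, e in enumerate(registries.get("key_parameters", []))
    )
    aspects = []
    for reg_key, reg_name in (("nm_aspects", "nm_aspect"), ("low_priority_properties", "low_priority_property")):
        for i, e in enumerate(registries.get(reg_key, [])):
            aspects.append(AspectEntry(
                name=str(e["name"]),
                mapped_criterion_ids=tuple(_parse_ref(r, f"{source}: {reg_key}[{i}]") for r in e.get("criteria", [])),
                registry=reg_name,
            ))
    return CriteriaBank(
        tool_name=str(data["tool_name"]),
        version=str(data["version"]),
        criteria=criteria,
        key_parameters=key_params,
        aspects=tuple(aspects),
    )


def _bank_to_dict(bank: CriteriaBank) -> dict:
    def crit(c: Criterion) -> dict:
        d: dict = {"id": c.id, "section": c.section}
        if c.text_available:
            d["text"] = c.text
        else:
            d["text_available"] = False
        if c.guidance:
            d["guidance"] = c.guidance
        if c.provenance != frozenset({"unchanged"}):
            d["provenance"] = sorted(c.provenance)
        if c.applicability_condition:
            d["applicability_condition"] = c.applicability_condition
        if c.open_ended:
            d["open_ended"] = True
        if c.tags:
            d["tags"] = list(c.tags)
        return d

    def refs(ids: Iterable[tuple[Part, int]]) -> list[str]:
        return [f"{p.value}{i}" for p, i in ids]

    registries: dict = {}
    if bank.key_parameters:
        registries["key_parameters"] = [
            {k: v for k, v in (("name", p.name), ("criteria", refs(p.mapped_criterion_ids)), ("note", p.note))
             if v is not None}
            for p in bank.key_parameters
        ]
    for reg_key, reg_name in (("nm_aspects", "nm_aspect"), ("low_priority_properties", "low_priority_property")):
        entries = [a for a in bank.aspects if a.registry == reg_name]
        if entries:
            registries[reg_key] = [{"name": a.name, "criteria": refs(a.mapped_criterion_ids)} for a in entries]
    return {
        "tool_name": bank.tool_name,
        "version": bank.version,
        "criteria": {p.value: [crit(c) for c in bank.part(p)] for p in Part if bank.part(p)},
        "registries": registries,
    }


def read_bank(path: str | Path) -> CriteriaBank:
    """Read a bank from a YAML (canonical) or JSON (mirror) file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise BankFileError(f"{path}: cannot parse: {exc}") from exc
    return _bank_from_dict(data, str(path))


def write_bank(bank: CriteriaBank, path: str | Path) -> Path:
    """Write a bank to YAML or JSON, chosen by the file suffix."""
    path = Path(path)
    data = _bank_to_dict(bank)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True), encoding="utf-8")
    return path


def load_builtin_bank(version: str) -> CriteriaBank:
    """Load one of the packaged banks (``"2.0"`` or ``"1.0-skeleton"``)."""
    if version not in BUILTIN_VERSIONS:
        raise UnsupportedBankVersionError(
            f"unsupported bank version {version!r}; available: {', '.join(BUILTIN_VERSIONS)}")
    ref = resources.files("scirapnano.data") / f"bank-{version}.yaml"
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    bank = _bank_from_dict(data, f"builtin:{version}")
    return bank
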