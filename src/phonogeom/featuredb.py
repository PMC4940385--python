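"""Feature tables, language inventories, and their binary encodings.

A segment database pairs a *feature system* — every segment label mapped to a
vector of binary articulatory feature values, encoded ±1 — with per-language
segment lists.  This module parses and writes both, extracts subsystems
(consonants, vowels, stops/affricates), applies the encodability filter
(languages containing two segments with identical feature vectors cannot be
represented faithfully in the feature system and are dropped), and computes
the combo/feature frequency tables that drive the random-control generators.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: default mapping from table cell symbols to encoded feature values
DEFAULT_SYMBOL_MAP: dict[str, int] = {"+": 1, "−": -1, "-": -1}

SUBSYSTEMS = ("whole", "consonant", "stop_affricate", "vowel")


class FeatureTableError(ValueError):
    """Raised for malformed feature tables or inventory tables."""


@dataclass(frozen=True)
class FeatureSystem:
    """Feature names plus each segment label's ±1 value vector.

    Duplicate *encodings* (two labels sharing one vector) are permitted at
    the system level — real transcription-based databases contain them; they
    are handled per language by :func:`filter_encodable`.
    """

    feature_names: tuple[str, ...]
    segment_table: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        if k < 1:
            raise FeatureTableError("feature system needs at least one feature")
        if len(set(self.feature_names)) != k:
            raise FeatureTableError("duplicate feature names")
        for label, vec in self.segment_table.items():
            if len(vec) != k:
                raise FeatureTableError(
                    f"segment {label!r}: vector length {len(vec)} != {k} features"
                )
            if any(v not in (-1, 1) for v in vec):
                raise FeatureTableError(f"segment {label!r}: values must be ±1")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise FeatureTableError(f"unknown feature {name!r}") from None

    def vector(self, label: str) -> tuple[int, ...]:
        try:
            return self.segment_table[label]
        except KeyError:
            raise FeatureTableError(f"unknown segment label {label!r}") from None


@dataclass(frozen=True)
class LanguageInventory:
    """One language's segment list (or one subsystem of it)."""

    language_id: str
    subsystem: str
    segment_labels: frozenset[str]

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(f"unknown subsystem {self.subsystem!r}")


@dataclass(frozen=True)
class EncodedInventory:
    """A language × subsystem inventory as an s × K matrix of ±1 rows.

    After :func:`filter_encodable` the rows are pairwise distinct and s ≥ 2.
    """

    language_id: str
    subsystem: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not np.isin(m, (-1, 1)).all():
            raise ValueError("matrix values must be ±1")

    @property
    def s(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(frozen=True)
class SubsystemRule:
    """A conjunction of (feature name, required sign) conditions.

    An empty conjunction is the identity (whole inventory).
    """

    name: str
    conditions: tuple[tuple[str, int], ...] = ()

    def validate(self, fs: FeatureSystem) -> None:
        for feat, sign in self.conditions:
            fs.feature_index(feat)
            if sign not in (-1, 1):
                raise ValueError(f"rule {self.name!r}: sign must be ±1")

    def matches(self, vec: Sequence[int], fs: FeatureSystem) -> bool:
        return all(vec[fs.feature_index(f)] == sign for f, sign in self.conditions)


# Default subsystem predicates.  The field's conventional classes: vowels are
# [+syllabic]; consonants [−syllabic]; stops/affricates are non-sonorant,
# non-continuant consonants.  Editable by passing explicit rules.
DEFAULT_SUBSYSTEM_RULES: dict[str, SubsystemRule] = {
    "whole": SubsystemRule("whole", ()),
    "vowel": SubsystemRule("vowel", (("syllabic", 1),)),
    "consonant": SubsystemRule("consonant", (("syllabic", -1),)),
    "stop_affricate": SubsystemRule(
        "stop_affricate",
        (("syllabic", -1), ("sonorant", -1), ("continuant", -1)),
    ),
}


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def parse_feature_table(
    path: str | Path,
    symbol_map: Mapping[str, int] | None = None,
) -> FeatureSystem:
    """Parse a segment-by-feature table into a :class:`FeatureSystem`.

    Layout: header row = feature names, first column = segment label, cells
    drawn from ``symbol_map`` (default ``+``→+1, ``−``/``-``→−1).  Any other
    cell symbol is a hard parse error naming the offending row and column —
    silent coercion would corrupt the geometry downstream.
    """
    path = Path(path)
    smap = dict(DEFAULT_SYMBOL_MAP if symbol_map is None else symbol_map)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=_sniff_delimiter(path))
        try:
            header = next(reader)
        except StopIteration:
            raise FeatureTableError(f"{path}: empty file") from None
        feature_names = tuple(name.strip() for name in header[1:])
        if not feature_names:
            raise FeatureTableError(f"{path}: no feature columns")
        table: dict[str, tuple[int, ...]] = {}
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            label = row[0].strip()
            if label in table:
                raise FeatureTableError(
                    f"{path}: duplicate segment label {label!r} at row {rownum}"
                )
            if len(row) - 1 != len(feature_names):
                raise FeatureTableError(
                    f"{path}: row {rownum} ({label!r}) has {len(row) - 1} cells, "
                    f"expected {len(feature_names)}"
                )
            vec = []
            for colnum, cell in enumerate(row[1:]):
                sym = cell.strip()
                if sym not in smap:
                    raise FeatureTableError(
                        f"{path}: unknown symbol {sym!r} at row {rownum} "
                        f"(segment {label!r}), column {feature_names[colnum]!r}"
                    )
                vec.append(smap[sym])
            table[label] = tuple(vec)
    return FeatureSystem(feature_names, table)


def write_feature_table(fs: FeatureSystem, path: str | Path) -> None:
    """Write a FeatureSystem as TSV/CSV (inverse of :func:`parse_feature_table`)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    inv_map = {1: "+", -1: "-"}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["segment", *fs.feature_names])
        for label, vec in fs.segment_table.items():
            writer.writerow([label, *(inv_map[v] for v in vec)])


def parse_inventory_table(path: str | Path) -> list[LanguageInventory]:
    """Parse a long-format CSV with columns ``language_id, segment_label``."""
    path = Path(path)
    by_lang: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        if reader.fieldnames is None or not {
            "language_id",
            "segment_label",
        } <= set(reader.fieldnames):
            raise FeatureTableError(
                f"{path}: need columns language_id, segment_label"
            )
        for row in reader:
            by_lang.setdefault(row["language_id"].strip(), set()).add(
                row["segment_label"].strip()
            )
    return [
        LanguageInventory(lang, "whole", frozenset(labels))
        for lang, labels in sorted(by_lang.items())
    ]


def write_inventory_table(invs: Iterable[LanguageInventory], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_sniff_delimiter(path))
        writer.writerow(["language_id", "segment_label"])
        for inv in invs:
            for label in sorted(inv.segment_labels):
                writer.writerow([inv.language_id, label])


def extract_subsystem(
    inv: LanguageInventory, rule: SubsystemRule, fs: FeatureSystem
) -> LanguageInventory:
    """Return the subset of ``inv`` satisfying ``rule``, tagged with its name.

    May be empty; callers drop empty (or size-1) inventories, since the
    geometric statistics are undefined below two segments.
    """
    rule.validate(fs)
    kept = frozenset(
        lab for lab in inv.segment_labels if rule.matches(fs.vector(lab), fs)
    )
    return LanguageInventory(inv.language_id, rule.name, kept)


def filter_encodable(
    invs: Sequence[LanguageInventory], fs: FeatureSystem
) -> tuple[list[EncodedInventory], list[str]]:
    """Encode inventories, dropping languages the feature system cannot express.

    A language is rejected (for the given subsystem) iff two of its segments
    share one feature vector: such a language is not encodable, because the
    encoding would collapse a real contrast.  Rejection is independent per
    subsystem.  Inventories with fewer than two distinct segments are dropped
    with a logged warning (not counted as encodability rejections).
    """
    encoded: list[EncodedInventory] = []
    rejected: list[str] = []
    n_small = 0
    for inv in invs:
        vectors = [fs.vector(lab) for lab in sorted(inv.segment_labels)]
        if len(set(vectors)) < len(vectors):
            rejected.append(inv.language_id)
            continue
        if len(vectors) < 2:
            n_small += 1
            continue
        encoded.append(
            EncodedInventory(
                inv.language_id, inv.subsystem, np.array(vectors, dtype=np.int8)
            )
        )
    if n_small:
        logger.warning(
            "dropped %d inventories with fewer than 2 segments (subsystem %s)",
            n_small,
            invs[0].subsystem if invs else "?",
        )
    return encoded, rejected


@dataclass
class ComboFrequencies:
    """Attested feature-combination counts and per-feature value frequencies.

    ``counts[combo]`` is the number of languages whose inventory contains the
    combination (set semantics per language).  ``plus_probs[k]`` is the
    fraction of +1 values for feature k over all segment *tokens* pooled
    across languages, computed from raw (unreduced) encodings.
    """

    counts: dict[tuple[int, ...], int]
    plus_probs: np.ndarray
    n_languages: int
    n_tokens: int
    subsystem: str = "whole"

    combos: list[tuple[int, ...]] = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.combos = sorted(self.counts)
        self.weights = np.array([self.counts[c] for c in self.combos], dtype=float)

    @property
    def pool_size(self) -> int:
        return len(self.combos)


def combo_frequencies(invs: Sequence[EncodedInventory]) -> ComboFrequencies:
    """Count attested combos across languages and pool per-feature +1 rates."""
    if not invs:
        raise ValueError("combo_frequencies: empty inventory list")
    counts: dict[tuple[int, ...], int] = {}
    plus = np.zeros(invs[0].n_features, dtype=np.int64)
    n_tokens = 0
    for inv in invs:
        # rows are distinct within a filtered inventory, so per-row counting
        # is per-language set semantics
        for row in inv.matrix:
            combo = tuple(int(v) for v in row)
            counts[combo] = counts.get(combo, 0) + 1
        plus += (inv.matrix == 1).sum(axis=0)
        n_tokens += inv.s
    return ComboFrequencies(
        counts=counts,
        plus_probs=plus / n_tokens,
        n_languages=len(invs),
        n_tokens=n_tokens,
        subsystem=invs[0].subsystem,
    )
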