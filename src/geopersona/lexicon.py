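"""Open lexicon dictionary format and trait-weight tables.

Proprietary closed-vocabulary dictionaries (LIWC and its relatives) score a
document as, per psychological category, the proportion of tokens matching the
category's word list, where a trailing ``*`` on an entry matches any token
with that prefix.  This module defines an open file format with the same
matching semantics so any such dictionary can be dropped in:

* a header block delimited by ``%`` lines mapping numeric category ids to
  category names, then
* one entry per line: ``word<TAB>id[,id...]`` (an entry may belong to several
  categories; a trailing ``*`` marks a prefix wildcard).

Trait weights map category proportions to Big Five raw scores through a per
trait intercept and per-category coefficients (a weighted dot product).  The
published regression coefficients linking dictionary categories to
questionnaire-measured traits are not redistributable, so the weight table is
a configurable CSV input; a documented fixture table is shipped for the five
marker categories of the bundled open lexicon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from geopersona.errors import ConfigurationError, DataError

TRAITS = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)


@dataclass
class Lexicon:
    """Category name -> list of lowercase patterns (trailing ``*`` = prefix)."""

    categories: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categories:
            raise ConfigurationError("lexicon has no categories")
        for name, patterns in self.categories.items():
            for p in patterns:
                if p != p.lower():
                    raise ConfigurationError(
                        f"lexicon pattern {p!r} in {name!r} is not lowercase"
                    )

    @property
    def category_names(self) -> list[str]:
        return list(self.categories)

    def compile(self) -> dict[str, tuple[frozenset[str], tuple[str, ...]]]:
        """Split each category into (exact-token set, prefix tuple) for matching."""
        compiled = {}
        for name, patterns in self.categories.items():
            exact = frozenset(p for p in patterns if not p.endswith("*"))
            prefixes = tuple(p[:-1] for p in patterns if p.endswith("*"))
            compiled[name] = (exact, prefixes)
        return compiled


@dataclass
class TraitWeights:
    """Per-trait intercept and category -> coefficient map."""

    intercepts: dict[str, float]
    coefficients: dict[str, dict[str, float]]  # trait -> category -> coef

    def validate_against(self, lexicon: Lexicon) -> None:
        known = set(lexicon.category_names)
        for trait, coefs in self.coefficients.items():
            missing = set(coefs) - known
            if missing:
                raise ConfigurationError(
                    f"weights for {trait!r} reference categories absent from "
                    f"the lexicon: {sorted(missing)}"
                )

    @property
    def traits(self) -> list[str]:
        return list(self.intercepts)


def read_lexicon(path: str | Path) -> Lexicon:
    """Parse a dictionary file in the open format described in the module docstring."""
    lines = Path(path).read_text().splitlines()
    try:
        first = lines.index("%")
        second = lines.index("%", first + 1)
    except ValueError as exc:
        raise DataError(f"{path}: missing %% header delimiters") from exc
    id_to_name: dict[str, str] = {}
    for line in lines[first + 1 : second]:
        if not line.strip():
            continue
        cat_id, _, cat_name = line.partition("\t")
        if not cat_name:
            raise DataError(f"{path}: malformed header line {line!r}")
        if cat_name in id_to_name.values():
            raise DataError(f"{path}: duplicate category name {cat_name!r}")
        id_to_name[cat_id.strip()] = cat_name.strip()
    categories: dict[str, list[str]] = {name: [] for name in id_to_name.values()}
    for line in lines[second + 1 :]:
        if not line.strip():
            continue
        word, _, ids = line.partition("\t")
        if not ids:
            raise DataError(f"{path}: malformed entry line {line!r}")
        for cat_id in ids.split(","):
            cat_id = cat_id.strip()
            if cat_id not in id_to_name:
                raise DataError(f"{path}: unknown category id {cat_id!r}")
            categories[id_to_name[cat_id]].append(word.strip().lower())
    return Lexicon(categories={k: v for k, v in categories.items() if v})


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    names = lexicon.category_names
    out = ["%"]
    out += [f"{i + 1}\t{name}" for i, name in enumerate(names)]
    out.append("%")
    index = {name: str(i + 1) for i, name in enumerate(names)}
    entries: dict[str, list[str]] = {}
    for name, patterns in lexicon.categories.items():
        for p in patterns:
            entries.setdefault(p, []).append(index[name])
    for word in sorted(entries):
        out.append(f"{word}\t{','.join(entries[word])}")
    Path(path).write_text("\n".join(out) + "\n")


def read_weights(path: str | Path) -> TraitWeights:
    """Read a wide CSV: ``trait,intercept,<category columns...>``."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise DataError(f"{path}: empty weight table")
    cat_cols = [c for c in rows[0] if c not in ("trait", "intercept")]
    intercepts, coefficients = {}, {}
    for row in rows:
        trait = row["trait"]
        intercepts[trait] = float(row["intercept"])
        coefficients[trait] = {c: float(row[c]) for c in cat_cols}
    return TraitWeights(intercepts=intercepts, coefficients=coefficients)


def write_weights(weights: TraitWeights, path: str | Path) -> None:
    cats = sorted({c for m in weights.coefficients.values() for c in m})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trait", "intercept", *cats])
        for trait in weights.traits:
            coefs = weights.coefficients[trait]
            w.writerow(
                [trait, weights.intercepts[trait]] + [coefs.get(c, 0.0) for c in cats]
            )


def default_lexicon() -> Lexicon:
    """The bundled open fixture lexicon (five Big Five marker categories)."""
    with resources.as_file(
        resources.files("geopersona.data").joinpath("open_fixture.dic")
    ) as p:
        return read_lexicon(p)


def default_weights() -> TraitWeights:
    """The bundled fixture weight table matching :func:`default_lexicon`."""
    with resources.as_file(
        resources.files("geopersona.data").joinpath("trait_weights.csv")
    ) as p:
        return read_weights(p)
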