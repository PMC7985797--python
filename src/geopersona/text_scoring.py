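"""Geo-tagged short texts -> county-year Big Five percentile scores.

The scoring chain is: filter (per-author dedup, minimum length), assign each
message to a county by point-in-polygon, concatenate retained text per
county-year, match tokens against a closed-vocabulary lexicon to get category
proportions, take the weighted dot product with a trait-coefficient table to
get raw trait values, and percentile-rank the raw values across counties
within each year so traits are comparable between counties.

Tokenization is deliberately plain: lowercase, split on runs of
non-alphanumeric characters.  Stop-word removal and rule-based suffix
stripping are available but off by default — wildcard lexicon patterns
subsume most of what stemming would buy, and the recorded word count (the
language control variable downstream) is always the pre-removal count.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.errors import GEOSException
from sklearn.base import BaseEstimator, TransformerMixin

from geopersona.errors import DataError, DegenerateError, InsufficientDataError
from geopersona.lexicon import Lexicon, TraitWeights, TRAITS
from geopersona.simulate import _percentile_within

_TOKEN_RE = re.compile(r"[^0-9a-z]+")
_APOSTROPHE_RE = re.compile(r"['’]")  # contractions collapse: don't -> dont

#: suffixes stripped (longest first) by the optional rule-based stemmer
_SUFFIXES = ("ing", "edly", "ed", "es", "s", "ly")


@dataclass(frozen=True)
class TweetRecord:
    author: str
    ts: str
    lat: float
    lon: float
    text: str

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise DataError(f"coordinates out of range: ({self.lat}, {self.lon})")


def read_tweets_jsonl(path: str | Path) -> list[TweetRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                records.append(
                    TweetRecord(d["author"], d["ts"], d["lat"], d["lon"], d["text"])
                )
    return records


def tokenize(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    stem: bool = False,
) -> list[str]:
    """Lowercase and split on non-alphanumeric runs; optional stop-list and stemming."""
    tokens = [t for t in _TOKEN_RE.split(_APOSTROPHE_RE.sub("", text.lower())) if t]
    if stopwords:
        tokens = [t for t in tokens if t not in stopwords]
    if stem:
        tokens = [_strip_suffix(t) for t in tokens]
    return tokens


def _strip_suffix(token: str) -> str:
    for suf in _SUFFIXES:
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            return token[: -len(suf)]
    return token


def filter_tweets(records: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Drop per-author duplicate texts (earliest kept) and tweets under 3 tokens.

    Duplicate detection is on the tokenized (normalized) text, per author;
    the same text by two different authors is retained twice.
    """
    best: dict[tuple[str, tuple[str, ...]], TweetRecord] = {}
    order: list[tuple[str, tuple[str, ...]]] = []
    for rec in records:
        toks = tuple(tokenize(rec.text))
        if len(toks) < 3:
            continue
        key = (rec.author, toks)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.ts < best[key].ts:
            best[key] = rec
    return [best[k] for k in order]


class CountyIndex:
    """Point-in-polygon lookup over a GeoJSON FeatureCollection keyed by fips.

    Boundary points count as inside; a point on a shared edge is assigned to
    the first matching feature in file order.
    """

    def __init__(self, collection: dict):
        self.fips: list[str] = []
        self.geoms = []
        for feat in collection["features"]:
            try:
                geom = shape(feat["geometry"])
            except (GEOSException, ValueError, KeyError, TypeError) as exc:
                raise DataError(f"malformed polygon feature: {exc}") from exc
            if not geom.is_valid:
                raise DataError(
                    f"invalid polygon ring for fips "
                    f"{feat.get('properties', {}).get('fips')!r}"
                )
            self.fips.append(feat["properties"]["fips"])
            self.geoms.append(geom)

    @classmethod
    def from_file(cls, path: str | Path) -> "CountyIndex":
        return cls(json.loads(Path(path).read_text()))

    def assign(self, lat: float, lon: float) -> str | None:
        pt = Point(lon, lat)
        for fips, geom in zip(self.fips, self.geoms):
            if geom.covers(pt):  # covers = boundary-inclusive containment
                return fips
        return None


def assign_county(lat: float, lon: float, polygons: dict | CountyIndex) -> str | None:
    if not isinstance(polygons, CountyIndex):
        polygons = CountyIndex(polygons)
    return polygons.assign(lat, lon)


@dataclass
class CountyDocument:
    fips: str
    year: int
    text: str
    word_count: int


def build_documents(
    records: Iterable[TweetRecord],
    polygons: dict | CountyIndex,
    stopwords: frozenset[str] | None = None,
    stem: bool = False,
) -> list[CountyDocument]:
    """Concatenate retained tweets per (county, UTC calendar year).

    ``word_count`` is the pre-stop-word-removal token count of the
    concatenated text (the language control variable downstream).
    """
    index = polygons if isinstance(polygons, CountyIndex) else CountyIndex(polygons)
    texts: dict[tuple[str, int], list[str]] = {}
    for rec in records:
        fips = index.assign(rec.lat, rec.lon)
        if fips is None:
            continue
        year = int(rec.ts[:4])  # ISO-8601; year attribution in UTC
        texts.setdefault((fips, year), []).append(rec.text)
    docs = []
    for (fips, year), parts in sorted(texts.items()):
        text = " ".join(parts)
        docs.append(
            CountyDocument(fips, year, text, word_count=len(tokenize(text)))
        )
    return docs


def score_categories(
    doc: CountyDocument,
    lexicon: Lexicon,
    stopwords: frozenset[str] | None = None,
    stem: bool = False,
) -> dict[str, float]:
    """Category -> matched-token proportion; a token may match several categories."""
    tokens = tokenize(doc.text, stopwords=stopwords, stem=stem)
    if not tokens:
        raise DegenerateError(f"document {doc.fips}/{doc.year} has no tokens")
    compiled = lexicon.compile()
    counts = dict.fromkeys(compiled, 0)
    # match distinct tokens once; documents repeat a small vocabulary heavily
    for tok, mult in Counter(tokens).items():
        for name, (exact, prefixes) in compiled.items():
            if tok in exact or any(tok.startswith(p) for p in prefixes):
                counts[name] += mult
    n = len(tokens)
    return {name: c / n for name, c in counts.items()}


def score_traits(
    props: dict[str, float], weights: TraitWeights
) -> dict[str, float]:
    """raw_t = intercept_t + sum_c coef_{t,c} * proportion_c."""
    out = {}
    for trait in weights.traits:
        coefs = weights.coefficients[trait]
        missing = [c for c in coefs if c not in props and coefs[c] != 0.0]
        if missing:
            raise DataError(f"missing category proportions for {trait}: {missing}")
        out[trait] = weights.intercepts[trait] + sum(
            coef * props.get(cat, 0.0) for cat, coef in coefs.items() if coef != 0.0
        )
    return out


def percentile_transform(raw: Sequence[float]) -> np.ndarray:
    """Average-rank percentile within a year: 100 * (rank - 0.5) / n, ties averaged."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise InsufficientDataError("percentile ranking needs >= 2 counties")
    return _percentile_within(raw)


class LexiconTraitScorer(BaseEstimator, TransformerMixin):
    """Score county-year documents into Big Five raw and percentile values.

    A scikit-learn transformer over a sequence of :class:`CountyDocument`;
    ``transform`` returns a DataFrame with one row per document: ``fips``,
    ``year``, ``word_count``, per-trait raw scores (``raw_<trait>``) and
    within-year percentiles (named by trait).

    Parameters
    ----------
    lexicon, weights : the dictionary and trait-coefficient table; defaults
        to the bundled open fixture pair when None.
    stopwords : optional stop-list applied before category matching (word
        counts stay pre-removal).
    stem : apply the rule-based suffix stripper before matching.
    """

    def __init__(self, lexicon=None, weights=None, stopwords=None, stem=False):
        self.lexicon = lexicon
        self.weights = weights
        self.stopwords = stopwords
        self.stem = stem

    def fit(self, X=None, y=None):
        from geopersona.lexicon import default_lexicon, default_weights

        self.lexicon_ = self.lexicon if self.lexicon is not None else default_lexicon()
        self.weights_ = self.weights if self.weights is not None else default_weights()
        self.weights_.validate_against(self.lexicon_)
        return self

    def transform(self, X: Sequence[CountyDocument]) -> pd.DataFrame:
        if not hasattr(self, "lexicon_"):
            self.fit()
        stopset = frozenset(self.stopwords) if self.stopwords else None
        rows = []
        for doc in X:
            props = score_categories(doc, self.lexicon_, stopset, self.stem)
            raw = score_traits(props, self.weights_)
            rows.append(
                {"fips": doc.fips, "year": doc.year, "word_count": doc.word_count,
                 **{f"raw_{t}": v for t, v in raw.items()}}
            )
        df = pd.DataFrame(rows)
        for trait in self.weights_.traits:
            df[trait] = np.nan
            for year, idx in df.groupby("year").groups.items():
                df.loc[idx, trait] = percentile_transform(
                    df.loc[idx, f"raw_{trait}"].to_numpy()
                )
        return df


def score_corpus(
    tweets_path: str | Path,
    polygons_path: str | Path,
    lexicon: Lexicon | None = None,
    weights: TraitWeights | None = None,
    stopwords: frozenset[str] | None = None,
    stem: bool = False,
) -> pd.DataFrame:
    """File-level convenience wrapper: JSON-lines tweets + GeoJSON -> scores table."""
    records = filter_tweets(read_tweets_jsonl(tweets_path))
    docs = build_documents(records, CountyIndex.from_file(polygons_path))
    scorer = LexiconTraitScorer(
        lexicon=lexicon, weights=weights, stopwords=stopwords, stem=stem
    ).fit()
    return scorer.transform(docs)
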