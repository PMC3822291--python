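"""Grapheme inventories and pairwise predictor measures.

Two inventories are packaged: the 46 basic Hiragana characters in gojuon
order (5 vowel symbols, 40 consonant+vowel syllable symbols, and the
moraic nasal) and the 26 uppercase Latin letters in A-Z order. Each
grapheme carries its 1-based ordinal position, the phoneme decomposition
of its *name* (for Hiragana the name equals the pronunciation; for Latin
letters it is the letter name, e.g. B -> /b/ /i:/), and optionally a
subjective familiarity rating on a 1-7 scale.

Four pairwise predictors are computed over all unordered grapheme pairs:

- ordinality difference  |i - j| / (i + j)  of sequence positions,
- phonological similarity: number of shared name phonemes,
- visual similarity: a rated 1-5 lookup from a norm matrix, or
  alternatively a shape *difference* as the Hamming distance between
  11-dimensional binary distinctive-feature vectors (Latin only),
- familiarity difference |f_x - f_y|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grapheme",
    "GraphemeInventory",
    "SimilarityNorms",
    "GibsonFeatures",
    "load_inventory",
    "load_default_inventory",
    "enumerate_pairs",
    "ordinality_difference",
    "phonological_similarity",
    "visual_similarity",
    "gibson_shape_difference",
    "familiarity_difference",
    "predictor_table",
]

Script = Literal["hiragana", "latin"]

#: predictor column names as they appear in tables and reports
PREDICTORS_RATED = (
    "ordinality_difference",
    "phonological_similarity",
    "visual_similarity",
    "familiarity_difference",
)
PREDICTORS_GIBSON = (
    "ordinality_difference",
    "phonological_similarity",
    "shape_difference",
    "familiarity_difference",
)


@dataclass(frozen=True)
class Grapheme:
    symbol: str
    script: str
    position: int
    name_phonemes: tuple[str, ...]
    familiarity: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1: {self.position}")
        if not self.name_phonemes:
            raise ValueError(f"grapheme {self.symbol!r} has no name phonemes")


class SchemaError(ValueError):
    """A fixture file failed validation; the message lists offending rows."""


class GraphemeInventory:
    """An ordered grapheme inventory for one script."""

    EXPECTED_SIZE = {"hiragana": 46, "latin": 26}

    def __init__(self, script: str, graphemes: Iterable[Grapheme]):
        self.script = script
        self.graphemes: list[Grapheme] = sorted(graphemes, key=lambda g: g.position)
        problems = []
        positions = [g.position for g in self.graphemes]
        if len(set(positions)) != len(positions):
            dup = [p for p, c in Counter(positions).items() if c > 1]
            problems.append(f"duplicated positions: {sorted(dup)}")
        symbols = [g.symbol for g in self.graphemes]
        if len(set(symbols)) != len(symbols):
            dup = [s for s, c in Counter(symbols).items() if c > 1]
            problems.append(f"duplicated symbols: {sorted(dup)}")
        if positions and positions != list(range(1, len(positions) + 1)):
            problems.append("positions are not contiguous from 1")
        for g in self.graphemes:
            if g.script != script:
                problems.append(f"{g.symbol!r} has script {g.script!r}")
        expected = self.EXPECTED_SIZE.get(script)
        if expected is not None and len(self.graphemes) != expected:
            problems.append(
                f"{script} inventory has {len(self.graphemes)} entries, "
                f"expected {expected}"
            )
        if problems:
            raise SchemaError("; ".join(problems))
        self._by_symbol = {g.symbol: g for g in self.graphemes}

    def __len__(self) -> int:
        return len(self.graphemes)

    def __iter__(self):
        return iter(self.graphemes)

    def __getitem__(self, symbol: str) -> Grapheme:
        return self._by_symbol[symbol]

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.graphemes]

    def with_familiarity(self, ratings: Mapping[str, float]) -> "GraphemeInventory":
        """Return a copy with familiarity ratings attached per symbol."""
        return GraphemeInventory(
            self.script,
            [replace(g, familiarity=float(ratings[g.symbol])) for g in self.graphemes],
        )


def _parse_inventory_frame(script: str, df: pd.DataFrame) -> GraphemeInventory:
    required = {"symbol", "script", "position", "name_phonemes"}
    if not required.issubset(df.columns):
        raise SchemaError(f"inventory CSV needs columns {sorted(required)}")
    bad_rows = []
    graphemes = []
    for idx, row in df.iterrows():
        phonemes = tuple(
            p for p in str(row["name_phonemes"]).split("|") if p and p != "nan"
        )
        fam = row.get("familiarity")
        fam = None if fam is None or pd.isna(fam) else float(fam)
        try:
            graphemes.append(
                Grapheme(
                    symbol=str(row["symbol"]),
                    script=str(row["script"]),
                    position=int(row["position"]),
                    name_phonemes=phonemes,
                    familiarity=fam,
                )
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if bad_rows:
        raise SchemaError("; ".join(bad_rows))
    return GraphemeInventory(script, graphemes)


def load_inventory(script: Script, path: str | Path) -> GraphemeInventory:
    """Load a grapheme inventory fixture (CSV) and validate it."""
    return _parse_inventory_frame(script, pd.read_csv(path))


def load_default_inventory(script: Script) -> GraphemeInventory:
    """Load the packaged Hiragana or Latin inventory."""
    if script not in ("hiragana", "latin"):
        raise ValueError(f"unknown script: {script!r}")
    with resources.as_file(
        resources.files("synmap.data").joinpath(f"{script}.csv")
    ) as path:
        return load_inventory(script, path)


class SimilarityNorms:
    """A symmetric matrix of rated visual similarity (1-5 scale)."""

    def __init__(self, script: str, matrix: pd.DataFrame, source: str = "unspecified"):
        if list(matrix.index) != list(matrix.columns):
            raise ValueError("norm matrix must have identical row/column labels")
        vals = matrix.to_numpy(dtype=float)
        off = ~np.eye(len(matrix), dtype=bool)
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValueError("norm matrix must be symmetric")
        finite = vals[off][np.isfinite(vals[off])]
        if finite.size and (finite.min() < 1 or finite.max() > 5):
            raise ValueError("similarity ratings must lie in [1, 5]")
        self.script = script
        self.matrix = matrix
        self.source = source

    def lookup(self, a: str, b: str) -> float:
        for s in (a, b):
            if s not in self.matrix.index:
                raise KeyError(
                    f"no visual-similarity norm for pair ({a!r}, {b!r}): "
                    f"{s!r} missing"
                )
        return float(self.matrix.loc[a, b])

    @classmethod
    def from_csv(cls, script: str, path: str | Path, source: str = "file") -> "SimilarityNorms":
        return cls(script, pd.read_csv(path, index_col=0), source=source)

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path)


class GibsonFeatures:
    """Binary distinctive-feature vectors (11 dimensions) per Latin letter.

    The packaged table is a synthetic reconstruction in the style of
    Gibson's distinctive-feature chart, derived from the stroke geometry of
    standard uppercase forms; the published table can be dropped in as a
    schema-compatible CSV.
    """

    N_FEATURES = 11

    def __init__(self, table: pd.DataFrame):
        vals = table.to_numpy()
        if table.shape[1] != self.N_FEATURES:
            raise ValueError(f"feature table must have {self.N_FEATURES} columns")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature entries must be binary")
        self.table = table.astype(int)

    def vector(self, symbol: str) -> np.ndarray:
        if symbol not in self.table.index:
            raise KeyError(f"no shape features for letter {symbol!r}")
        return self.table.loc[symbol].to_numpy()

    @classmethod
    def from_csv(cls, path: str | Path) -> "GibsonFeatures":
        return cls(pd.read_csv(path, index_col=0))

    @classmethod
    def load_default(cls) -> "GibsonFeatures":
        with resources.as_file(
            resources.files("synmap.data").joinpath("gibson_features.csv")
        ) as path:
            return cls.from_csv(path)


def enumerate_pairs(inventory: GraphemeInventory) -> list[tuple[Grapheme, Grapheme]]:
    """All unordered distinct grapheme pairs, ordered by (position_i, position_j).

    Yields n(n-1)/2 pairs with the lower-position grapheme first.
    """
    return list(combinations(inventory.graphemes, 2))


def ordinality_difference(i: int, j: int) -> float:
    """|i - j| / (i + j) for two 1-based sequence positions; in (0, 1)."""
    if i < 1 or j < 1:
        raise ValueError("positions must be >= 1")
    if i == j:
        raise ValueError("ordinality difference is undefined for a self-pair")
    return abs(i - j) / (i + j)


def phonological_similarity(x: Grapheme, y: Grapheme) -> int:
    """Number of shared name phonemes (multiset intersection, order-free)."""
    return sum((Counter(x.name_phonemes) & Counter(y.name_phonemes)).values())


def visual_similarity(
    pair: tuple[Grapheme, Grapheme], norms: SimilarityNorms
) -> float:
    """Rated visual similarity of a pair (symmetric 1-5 lookup)."""
    return norms.lookup(pair[0].symbol, pair[1].symbol)


def gibson_shape_difference(
    x: Grapheme, y: Grapheme, features: GibsonFeatures
) -> int:
    """Hamming distance between two letters' binary shape-feature vectors."""
    return int(np.sum(features.vector(x.symbol) != features.vector(y.symbol)))


def familiarity_difference(x: Grapheme, y: Grapheme) -> float:
    """Absolute difference of the two graphemes' familiarity ratings."""
    if x.familiarity is None or y.familiarity is None:
        missing = [g.symbol for g in (x, y) if g.familiarity is None]
        raise ValueError(f"familiarity rating missing for {missing}")
    return abs(x.familiarity - y.familiarity)


def predictor_table(
    inventory: GraphemeInventory,
    norms: SimilarityNorms | None = None,
    features: GibsonFeatures | None = None,
    shape_measure: Literal["rated", "gibson"] = "rated",
) -> pd.DataFrame:
    """Per-pair predictor values for every unordered grapheme pair.

    Returns one row per pair with columns ``symbol_a``, ``symbol_b``, the
    ordinality difference, phonological similarity, the chosen shape
    measure (``visual_similarity`` from rated norms, or
    ``shape_difference`` from binary feature vectors) and the familiarity
    difference.
    """
    if shape_measure == "rated":
        if norms is None:
            raise ValueError("rated shape measure requires similarity norms")
        shape_col = "visual_similarity"
    elif shape_measure == "gibson":
        if features is None:
            raise ValueError("gibson shape measure requires a feature table")
        if inventory.script != "latin":
            raise ValueError("the binary shape-feature measure is Latin-only")
        shape_col = "shape_difference"
    else:
        raise ValueError(f"unknown shape_measure: {shape_measure!r}")

    rows = []
    for x, y in enumerate_pairs(inventory):
        if shape_measure == "rated":
            shape_val = visual_similarity((x, y), norms)
        else:
            shape_val = gibson_shape_difference(x, y, features)
        rows.append(
            {
                "symbol_a": x.symbol,
                "symbol_b": y.symbol,
                "ordinality_difference": ordinality_difference(x.position, y.position),
                "phonological_similarity": phonological_similarity(x, y),
                shape_col: shape_val,
                "familiarity_difference": familiarity_difference(x, y),
            }
        )
    return pd.DataFrame(rows)
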