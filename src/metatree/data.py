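"""Core data containers for meta-analytic tree modelling.

The unit of analysis is a meta-analytic dataset: one row per study with an
observed effect size (a standardized mean difference ``d``), its within-study
sampling variance, and a set of typed moderator columns (study features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised moderator types.
MODERATOR_TYPES = ("binary", "nominal", "ordinal", "continuous")

# internal numeric type codes used by the tree kernels
_TYPE_THRESHOLD = 0  # binary / ordinal / continuous: ordered, split by "<= t"
_TYPE_NOMINAL = 1    # unordered levels, split by subset


@dataclass
class EffectSizeSet:
    """A meta-analytic dataset: per-study effect sizes, variances, moderators.

    Parameters
    ----------
    d : array-like of float
        Observed effect sizes (standardized mean differences), one per study.
    var : array-like of float
        Within-study sampling variances, strictly positive.
    X : pandas.DataFrame
        Moderator matrix, one row per study.  Column dtypes are free; the
        interpretation of each column is given by ``types``.
    types : dict mapping column name -> type tag
        One of ``binary``, ``nominal``, ``ordinal``, ``continuous``.
    ordinal_levels : dict, optional
        For ordinal columns, the explicit level order (low to high).  When
        absent, the sorted unique values are used.
    ids : sequence, optional
        Study labels; defaults to 0..K-1.
    level_maps : dict, optional
        Pre-assigned level -> code order per categorical column.  Used when a
        dataset is a row-subset of another (e.g. a cross-validation fold) so
        that split rules learned on the subset live in the parent's code
        space.  Normally left unset.
    """

    d: np.ndarray
    var: np.ndarray
    X: pd.DataFrame
    types: dict
    ordinal_levels: dict = field(default_factory=dict)
    ids: Sequence | None = None
    level_maps: dict | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.d.ndim != 1 or self.var.ndim != 1:
            raise ValueError("d and var must be one-dimensional")
        if len(self.d) != len(self.var):
            raise ValueError("d and var must have equal length")
        if len(self.d) == 0:
            raise ValueError("empty dataset")
        if np.any(~np.isfinite(self.d)) or np.any(~np.isfinite(self.var)):
            raise ValueError("non-finite effect size or variance")
        if np.any(self.var <= 0):
            bad = np.flatnonzero(self.var <= 0).tolist()
            raise ValueError(f"nonpositive sampling variance at rows {bad}")
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(self.X)
        if len(self.X) != len(self.d):
            raise ValueError("moderator matrix row count does not match d")
        for col in self.X.columns:
            if col not in self.types:
                raise ValueError(f"no type tag for moderator {col!r}")
            if self.types[col] not in MODERATOR_TYPES:
                raise ValueError(f"unknown moderator type {self.types[col]!r}")
        if self.ids is None:
            self.ids = list(range(len(self.d)))
        self._encoded = None

    @property
    def K(self) -> int:
        """Number of studies."""
        return len(self.d)

    @property
    def M(self) -> int:
        """Number of moderators."""
        return self.X.shape[1]

    @property
    def w_fe(self) -> np.ndarray:
        """Fixed-effect weights 1/var."""
        return 1.0 / self.var

    # ---- numeric encoding used by the tree kernels -----------------------
    def encoded(self):
        """Return (codes, type_codes, n_levels, level_maps).

        ``codes`` is a float (K, M) matrix: binary columns coded 0/1,
        ordinal columns coded by their level rank (0..L-1), continuous left
        as-is, nominal coded by level index 0..L-1 (order arbitrary but
        deterministic).  ``type_codes`` marks each column as threshold-type
        or nominal.  ``level_maps`` maps column -> list of original levels
        in code order (for decoding split rules).
        """
        if self._encoded is not None:
            return self._encoded
        K, M = self.K, self.M
        codes = np.empty((K, M), dtype=float)
        type_codes = np.empty(M, dtype=np.int64)
        n_levels = np.zeros(M, dtype=np.int64)
        level_maps = {}
        for j, col in enumerate(self.X.columns):
            tag = self.types[col]
            vals = self.X[col]
            if tag == "continuous":
                codes[:, j] = pd.to_numeric(vals).to_numpy(dtype=float)
                type_codes[j] = _TYPE_THRESHOLD
            elif tag == "ordinal":
                levels = self.ordinal_levels.get(col)
                if levels is None and self.level_maps is not None:
                    levels = self.level_maps.get(col)
                if levels is None:
                    levels = sorted(pd.unique(vals))
                lookup = {lv: i for i, lv in enumerate(levels)}
                try:
                    codes[:, j] = [lookup[v] for v in vals]
                except KeyError as e:
                    raise ValueError(
                        f"value {e.args[0]!r} not in declared level order "
                        f"for ordinal moderator {col!r}"
                    ) from None
                type_codes[j] = _TYPE_THRESHOLD
                level_maps[col] = list(levels)
            elif tag == "binary":
                levels = None if self.level_maps is None else self.level_maps.get(col)
                if levels is None:
                    levels = sorted(pd.unique(vals), key=repr)
                if len(levels) > 2:
                    raise ValueError(f"binary moderator {col!r} has >2 levels")
                lookup = {lv: i for i, lv in enumerate(levels)}
                codes[:, j] = [lookup[v] for v in vals]
                type_codes[j] = _TYPE_THRESHOLD
                level_maps[col] = list(levels)
            else:  # nominal
                levels = None if self.level_maps is None else self.level_maps.get(col)
                if levels is None:
                    levels = sorted(pd.unique(vals), key=repr)
                lookup = {lv: i for i, lv in enumerate(levels)}
                codes[:, j] = [lookup[v] for v in vals]
                type_codes[j] = _TYPE_NOMINAL
                n_levels[j] = len(levels)
                level_maps[col] = list(levels)
        self._encoded = (codes, type_codes, n_levels, level_maps)
        return self._encoded

    def subset(self, idx) -> "EffectSizeSet":
        """Row-subset (e.g. a cross-validation fold).

        Types, ordinal level orders and level -> code maps are inherited so
        split rules learned on the subset are expressed in the parent's code
        space.
        """
        idx = np.asarray(idx)
        _, _, _, maps = self.encoded()
        return EffectSizeSet(
            d=self.d[idx],
            var=self.var[idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            types=dict(self.types),
            ordinal_levels=dict(self.ordinal_levels),
            ids=[self.ids[i] for i in idx],
            level_maps=dict(maps),
        )


@dataclass
class SubgroupPartition:
    """Assignment of each study to one of J non-empty subgroups."""

    assignment: np.ndarray
    J: int

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.J < 1:
            raise ValueError("J must be >= 1")
        counts = np.bincount(self.assignment, minlength=self.J)
        if self.assignment.min(initial=0) < 0 or self.assignment.max(initial=0) >= self.J:
            raise ValueError("assignment indices out of range")
        if np.any(counts == 0):
            raise ValueError("every subgroup must be non-empty")

    @classmethod
    def from_labels(cls, labels) -> "SubgroupPartition":
        labels = np.asarray(labels)
        _, assignment = np.unique(labels, return_inverse=True)
        return cls(assignment=assignment, J=int(assignment.max()) + 1)
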