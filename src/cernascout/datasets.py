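"""Core in-memory containers shared across the pipeline.

Expression data travel as :class:`ExpressionDataset` (a labelled genes x
samples matrix), gene sets as :class:`GeneSetCollection`.  Both validate
their invariants at construction time so downstream stages can assume a
clean state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("mRNA", "lncRNA", "miRNA")
VALID_GROUPS = ("control", "case")


class FormatError(ValueError):
    """A file or container violates the expected format."""


@dataclass
class ExpressionDataset:
    """One cohort's expression matrix with sample and feature metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Features (rows) x samples (columns), log2 scale unless
        ``is_log`` is False.
    biotype : pandas.Series
        Per-feature biotype, one of ``mRNA``, ``lncRNA``, ``miRNA``,
        indexed like ``values``.
    group : pandas.Series
        Per-sample group label, ``control`` or ``case``, indexed by
        sample id.
    cohort_id : str
        Identifier of the cohort (e.g. a GEO accession or a synthetic
        cohort name).
    is_log : bool
        Whether values are already on log2 scale.  Raw intensities are
        transformed by ``log2(x + 1)`` during preprocessing.
    """

    values: pd.DataFrame
    biotype: pd.Series
    group: pd.Series
    cohort_id: str = "cohort"
    is_log: bool = True

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise FormatError(f"cohort {self.cohort_id!r}: empty expression matrix")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()][0]
            raise FormatError(f"feature {missing!r} has no biotype")
        bad = set(self.biotype.unique()) - set(VALID_BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotype(s): {sorted(bad)}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()][0]
            raise FormatError(f"unlabeled sample {missing!r}")
        bad = set(self.group.unique()) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_mask(self) -> np.ndarray:
        return (self.group == "case").to_numpy()

    def subset_biotype(self, biotype: str) -> "ExpressionDataset":
        """Restrict to features of one biotype (feature order preserved)."""
        keep = self.biotype == biotype
        if not keep.any():
            raise FormatError(
                f"cohort {self.cohort_id!r} has no {biotype} features"
            )
        return ExpressionDataset(
            values=self.values.loc[keep],
            biotype=self.biotype.loc[keep],
            group=self.group.copy(),
            cohort_id=self.cohort_id,
            is_log=self.is_log,
        )

    def with_values(self, values: pd.DataFrame, is_log: bool | None = None) -> "ExpressionDataset":
        """Return a copy carrying new values but the same metadata."""
        return ExpressionDataset(
            values=values,
            biotype=self.biotype.copy(),
            group=self.group.reindex(values.columns),
            cohort_id=self.cohort_id,
            is_log=self.is_log if is_log is None else is_log,
        )

    def require_two_per_group(self) -> None:
        counts = self.group.value_counts()
        for level in VALID_GROUPS:
            if counts.get(level, 0) < 2:
                raise FormatError(
                    f"cohort {self.cohort_id!r}: fewer than 2 {level!r} samples"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) with descriptions."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]
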