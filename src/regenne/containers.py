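"""In-memory containers for expression data, gene sets and phenotypes.

The canonical orientation everywhere in this package is rows = samples,
columns = genes. Gene symbols are upper-cased on ingestion so that
expression headers match gene-set files regardless of capitalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric matrix with identifiers on both axes.

    Values are unitless log-scale expression (e.g. log2(x+1)-transformed
    normalized counts); the package never re-normalizes them.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {n} value rows"
            )
        if g != len(self.gene_ids):
            raise ValidationError(f"{len(self.gene_ids)} gene ids but {g} value columns")
        self.gene_ids = [str(gid).upper() for gid in self.gene_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids (after upper-casing)")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at sample row {bad[0]}, gene column {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            sample_ids=[str(s) for s in df.index],
            gene_ids=[str(g) for g in df.columns],
            values=df.to_numpy(dtype=np.float64),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), list(self.gene_ids), self.values[rows])


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.name!r} has an empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"pathway {self.name!r} lists a gene twice")


@dataclass
class PathwayCollection:
    """Ordered, named gene sets; pathways may share genes."""

    entries: dict[str, Pathway] = field(default_factory=dict)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Sequence[str]], descriptions: Mapping[str, str] | None = None
    ) -> "PathwayCollection":
        coll = cls()
        for name, genes in mapping.items():
            desc = (descriptions or {}).get(name, "")
            coll.add(name, desc, genes)
        return coll

    def add(self, name: str, description: str, genes: Sequence[str]) -> None:
        if name in self.entries:
            raise ValidationError(f"duplicate pathway name {name!r}")
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(str(g).upper())
        self.entries[name] = Pathway(name, description, tuple(seen))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.entries.values())

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> Pathway:
        return self.entries[name]

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.entries[name].genes

    def overlap(self, a: str, b: str) -> set[str]:
        return set(self.entries[a].genes) & set(self.entries[b].genes)

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for pw in self:
            for g in pw.genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class PhenotypeTable:
    """Binary labels (0/1) keyed by sample id."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        for sid, y in self.labels.items():
            if y not in (0, 1):
                raise ValidationError(f"label for sample {sid!r} is {y!r}, not in {{0, 1}}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def to_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids], dtype=np.int64)

    def class_counts(self) -> tuple[int, int]:
        vals = list(self.labels.values())
        return vals.count(0), vals.count(1)

    def require_both_classes(self) -> None:
        n0, n1 = self.class_counts()
        if n0 == 0 or n1 == 0:
            raise ValidationError("both phenotype classes must be present")
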