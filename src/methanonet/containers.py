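"""Core in-memory containers shared by all pipeline stages.

The taxon unit throughout is the OTU (operational taxonomic unit, 97 %
16S rRNA identity cluster).  Count tables are held OTU x sample, the
amplicon convention, with a SILVA-style semicolon-delimited lineage per
OTU whose first rank gives the domain (Archaea or Bacteria).  Relative
abundances are always computed within a domain, because archaeal and
bacterial libraries are sequenced and rarefied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

DOMAINS = ("Archaea", "Bacteria")

#: Metadata column order used by every writer/reader.
METADATA_COLUMNS = (
    "sample_id",
    "soil",
    "pre_temp",
    "inc_temp",
    "replicate",
    "phase",
    "treatment_code",
)


def domain_from_lineage(lineage: str) -> str:
    """First rank of a semicolon-delimited lineage, rank prefixes stripped."""
    first = lineage.split(";")[0].strip()
    if "__" in first:  # tolerate "d__Archaea" style prefixes
        first = first.split("__", 1)[1]
    if first not in DOMAINS:
        raise ValueError(
            f"cannot derive domain from lineage {lineage!r}: "
            f"first rank {first!r} is not one of {DOMAINS}"
        )
    return first


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id, one column per sample, integer dtype.
    taxonomy
        Series of semicolon-delimited lineages indexed like ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    domain: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        if not self.taxonomy.index.equals(self.counts.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
            if self.taxonomy.isna().any():
                missing = self.taxonomy.index[self.taxonomy.isna()].tolist()
                raise ValueError(f"OTUs missing taxonomy: {missing}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.domain = self.taxonomy.map(domain_from_lineage)

    # ------------------------------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        ids = pd.Index(otu_ids)
        return OtuTable(self.counts.loc[ids].copy(), self.taxonomy.loc[ids].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        return OtuTable(self.counts.loc[:, ids].copy(), self.taxonomy.copy())

    def domain_table(self, domain: str) -> "OtuTable":
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        mask = self.domain == domain
        return OtuTable(self.counts.loc[mask].copy(), self.taxonomy.loc[mask].copy())

    def drop_singletons(self) -> "OtuTable":
        """Remove OTUs whose total count over all samples is exactly one."""
        keep = self.counts.sum(axis=1) != 1
        return OtuTable(self.counts.loc[keep].copy(), self.taxonomy.loc[keep].copy())

    def relative_abundance(self, per_domain: bool = True) -> pd.DataFrame:
        """Proportions per sample; within each domain when ``per_domain``.

        Archaeal proportions are relative to archaeal reads (and likewise
        for Bacteria) because the two domains are sequenced separately.
        """
        out = self.counts.astype(float).copy()
        if per_domain:
            for dom in DOMAINS:
                mask = (self.domain == dom).to_numpy()
                if not mask.any():
                    continue
                tot = out.loc[mask].sum(axis=0)
                out.loc[mask] = out.loc[mask].div(tot.replace(0.0, np.nan), axis=1)
        else:
            tot = out.sum(axis=0)
            out = out.div(tot.replace(0.0, np.nan), axis=1)
        return out.fillna(0.0)


@dataclass(frozen=True)
class TreatmentCode:
    """Treatment designation like ``I45e25``: soil letter, pre-incubation
    temperature, and (for temperature-shift samples) incubation temperature.
    A bare ``I45`` denotes a pre-incubation-phase sample."""

    soil: str
    pre_temp: int
    inc_temp: int | None = None

    def render(self) -> str:
        if self.inc_temp is None:
            return f"{self.soil}{self.pre_temp}"
        return f"{self.soil}{self.pre_temp}e{self.inc_temp}"


@dataclass
class CoNetwork:
    """Weighted undirected co-occurrence network over OTUs.

    Node attributes: ``taxonomy``, ``domain``, ``module``, ``temperature``
    (module temperature label), ``x``/``y`` layout coordinates.
    Edge attributes: ``weight`` (Spearman rho), ``p``, ``q``.
    """

    graph: nx.Graph
    modularity: float | None = None
    module_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def modules(self) -> dict[str, int]:
        return {n: d["module"] for n, d in self.graph.nodes(data=True)}

    def major_modules(self, min_fraction: float = 0.10) -> list[int]:
        """Module ids holding at least ``min_fraction`` of network nodes."""
        if self.n_nodes == 0:
            return []
        sizes: dict[int, int] = {}
        for _, d in self.graph.nodes(data=True):
            sizes[d["module"]] = sizes.get(d["module"], 0) + 1
        cut = min_fraction * self.n_nodes
        return sorted(m for m, s in sizes.items() if s >= cut)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check column set and dtypes of a sample metadata frame."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    md = metadata.loc[:, list(METADATA_COLUMNS)].copy()
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    pre_mask = md["phase"] == "pre"
    if md.loc[pre_mask, "inc_temp"].notna().any():
        raise ValueError("pre-incubation-phase samples must have inc_temp absent")
    return md


def effective_temperature(row: Mapping) -> float:
    """Temperature governing the thermal response of a sample.

    Pre-incubation samples respond to the pre-incubation temperature;
    shift-phase samples respond to the incubation temperature (the
    hysteresis legacy of the pre-incubation is handled separately).
    """
    if row["phase"] == "pre" or pd.isna(row["inc_temp"]):
        return float(row["pre_temp"])
    return float(row["inc_temp"])
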