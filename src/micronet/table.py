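"""Sample-by-taxon count tables with sample metadata.

The :class:`AbundanceTable` is the pipeline's universal input: an integer
count matrix (samples x taxa) plus per-sample metadata (group label,
timepoint, negative-control flag).  Tables round-trip through two plain-text
formats: a TSV with taxa as rows and samples as columns (the layout QIIME2
exports after genus-level collapse) and a BIOM v1 JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """Integer count matrix with per-sample metadata.

    Parameters
    ----------
    counts :
        DataFrame of shape (n_samples, n_taxa); non-negative integers.
        Index = sample ids, columns = taxon ids.
    metadata :
        DataFrame indexed by sample id with columns ``group``,
        ``timepoint`` and ``is_control`` (bool).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {
                    "group": "all",
                    "timepoint": "all",
                    "is_control": False,
                },
                index=self.counts.index,
            )
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.counts.index]
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.is_unique:
            raise ValueError("taxon ids must be unique")

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def group_of(self, sample: str) -> str:
        return self.metadata.at[sample, "group"]

    def is_control(self, sample: str) -> bool:
        return bool(self.metadata.at[sample, "is_control"])

    def controls(self) -> "AbundanceTable":
        """Sub-table of negative-control samples."""
        return self.subset_samples(self.metadata.index[self.metadata["is_control"]])

    def true_samples(self) -> "AbundanceTable":
        """Sub-table of biological (non-control) samples."""
        return self.subset_samples(self.metadata.index[~self.metadata["is_control"]])

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy())

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        ids = list(taxon_ids)
        return AbundanceTable(self.counts[ids].copy(), self.metadata.copy())

    def group_samples(self, group: str, timepoint: str | None = None) -> "AbundanceTable":
        """Sub-table of true samples in *group* (optionally at *timepoint*)."""
        md = self.metadata
        mask = (md["group"] == group) & (~md["is_control"].astype(bool))
        if timepoint is not None:
            mask &= md["timepoint"] == timepoint
        if not mask.any():
            raise KeyError(f"no samples for group {group!r}"
                           + (f" at timepoint {timepoint!r}" if timepoint else ""))
        return self.subset_samples(md.index[mask])

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, counts_path, metadata_path=None) -> None:
        """Write counts (taxa as rows, samples as columns) and metadata."""
        out = self.counts.T
        out.index.name = "taxon_id"
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            md = self.metadata.copy()
            md.index.name = "sample_id"
            md.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path=None) -> "AbundanceTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0).T
        counts.index.name = None
        counts = counts.astype(np.int64)
        metadata = None
        if metadata_path is not None:
            metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
            metadata["is_control"] = metadata["is_control"].astype(bool)
            metadata.index = metadata.index.astype(str)
            metadata.index.name = None
        counts.index = counts.index.astype(str)
        return cls(counts, metadata)

    def to_biom_json(self, path) -> None:
        """Write a BIOM v1 (JSON, dense) table with metadata on samples."""
        md = self.metadata
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "micronet",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_taxa, self.n_samples],
            "rows": [{"id": t, "metadata": None} for t in self.taxon_ids],
            "columns": [
                {
                    "id": s,
                    "metadata": {
                        "group": str(md.at[s, "group"]),
                        "timepoint": str(md.at[s, "timepoint"]),
                        "is_control": bool(md.at[s, "is_control"]),
                    },
                }
                for s in self.sample_ids
            ],
            "data": self.counts.to_numpy().T.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_biom_json(cls, path) -> "AbundanceTable":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        if doc["matrix_type"] == "dense":
            data = np.asarray(doc["data"], dtype=np.int64).T
        else:  # sparse [row, col, value]
            data = np.zeros((len(samples), len(taxa)), dtype=np.int64)
            for r, c, v in doc["data"]:
                data[c, r] = v
        counts = pd.DataFrame(data, index=samples, columns=taxa)
        meta = {}
        for c in doc["columns"]:
            m = c.get("metadata") or {}
            meta[c["id"]] = {
                "group": m.get("group", "all"),
                "timepoint": m.get("timepoint", "all"),
                "is_control": bool(m.get("is_control", False)),
            }
        metadata = pd.DataFrame.from_dict(meta, orient="index").loc[samples]
        return cls(counts, metadata)
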