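"""Tab-separated readers/writers shared by every pipeline stage.

All outputs carry a leading ``#``-prefixed header line recording the config
hash and master seed of the run that produced them; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd


def config_hash(config: Mapping) -> str:
    """Stable short hash of a (JSON-serialisable) configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, *, meta: Mapping | None = None,
              index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            items = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
            fh.write(f"# {items}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, *, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


@dataclass
class StageLabeledExpression:
    """Gene x sample log-expression with stage labels and gene classes.

    ``values`` rows are genes, columns samples. ``sample_stage`` maps each
    sample to an ordinal stage id (1..N). ``gene_class`` maps each gene to
    ``"lncRNA"`` or ``"mRNA"``; ``icp_flag`` marks immune-checkpoint genes.
    """

    values: pd.DataFrame
    sample_stage: pd.Series
    gene_class: pd.Series
    icp_flag: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.icp_flag is None:
            self.icp_flag = pd.Series(False, index=self.values.index)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = self.values.columns.difference(self.sample_stage.index)
        if len(missing):
            raise ValueError(f"samples without stage label: {list(missing)[:5]}")
        unclassed = self.values.index.difference(self.gene_class.index)
        if len(unclassed):
            raise ValueError(f"genes without class: {list(unclassed)[:5]}")
        self.sample_stage = self.sample_stage.loc[self.values.columns]
        self.gene_class = self.gene_class.loc[self.values.index]
        self.icp_flag = self.icp_flag.reindex(self.values.index, fill_value=False)

    @property
    def stages(self) -> list:
        return sorted(self.sample_stage.unique())

    def stage_samples(self, stage) -> pd.Index:
        return self.sample_stage.index[self.sample_stage == stage]

    def subset_samples(self, samples) -> "StageLabeledExpression":
        return StageLabeledExpression(
            values=self.values[list(samples)],
            sample_stage=self.sample_stage.loc[list(samples)],
            gene_class=self.gene_class,
            icp_flag=self.icp_flag,
        )

    def write(self, expr_path, clinical_path, catalog_path, *, meta=None,
              extra_clinical: pd.DataFrame | None = None) -> None:
        write_tsv(self.values.rename_axis("gene"), expr_path, meta=meta)
        clin = self.sample_stage.rename("stage").rename_axis("sample").to_frame()
        if extra_clinical is not None:
            clin = clin.join(extra_clinical)
        write_tsv(clin, clinical_path, meta=meta)
        cat = pd.DataFrame({
            "class": self.gene_class,
            "is_icp": self.icp_flag.astype(int),
        }).rename_axis("gene")
        write_tsv(cat, catalog_path, meta=meta)

    @classmethod
    def read(cls, expr_path, clinical_path, catalog_path) -> "StageLabeledExpression":
        values = read_tsv(expr_path)
        clin = read_tsv(clinical_path)
        cat = read_tsv(catalog_path)
        return cls(
            values=values,
            sample_stage=clin["stage"],
            gene_class=cat["class"],
            icp_flag=cat["is_icp"].astype(bool),
        )
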