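"""RT-qPCR relative quantification by the comparative Ct method.

Per sample and replicate, transcript levels (Ct) are normalized to the
housekeeping gene (ΔCt = Ct_gene − Ct_housekeeping), then to the mean ΔCt
of the reference sample for that gene (ΔΔCt), and reported as relative
quantities RQ = 2^−ΔΔCt with a fixed amplification efficiency of 2.
Replicates are carried through the whole computation and summarized as
mean ± SEM at the end, both on the ΔΔCt and the RQ scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DataError

__all__ = ["CtTable", "compute_rq"]

REQUIRED_COLUMNS = ("sample", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Tidy Ct measurements with the normalization scheme.

    ``data`` columns: sample, gene, replicate, ct (cycles). Every sample
    needs the housekeeping gene in each replicate, and the reference sample
    must be present.
    """

    data: pd.DataFrame
    housekeeping_gene: str = "GAPDH"
    reference_sample: str = "WT"

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.columns = [c.lower() for c in df.columns]
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"Ct table is missing columns: {missing}")
        df["ct"] = pd.to_numeric(df["ct"])
        if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
            raise DataError("all Ct values must be finite and positive")
        if self.reference_sample not in set(df["sample"]):
            raise DataError(f"reference sample {self.reference_sample!r} not in table")
        hk = df[df["gene"] == self.housekeeping_gene]
        for sample in df["sample"].unique():
            if sample not in set(hk["sample"]):
                raise DataError(
                    f"sample {sample!r} has no Ct for housekeeping gene "
                    f"{self.housekeeping_gene!r}"
                )
        self.data = df

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CtTable":
        return cls(pd.read_csv(path), **kwargs)


def compute_rq(table: CtTable) -> dict:
    """Relative quantities and their replicate summaries.

    Returns ``{"replicates": df, "summary": df}``: the first with one row
    per (sample, gene, replicate) carrying delta_ct, delta_delta_ct and rq;
    the second with mean ± SEM per (sample, gene) on both scales. The
    reference sample's mean ΔΔCt is 0 by construction, so its mean RQ on
    the ΔΔCt scale is 1.
    """
    df = table.data
    hk = (
        df[df["gene"] == table.housekeeping_gene]
        .set_index(["sample", "replicate"])["ct"]
        .rename("ct_hk")
    )
    genes = df[df["gene"] != table.housekeeping_gene].copy()
    if genes.empty:
        raise DataError("Ct table contains only the housekeeping gene")
    genes = genes.join(hk, on=["sample", "replicate"])
    if genes["ct_hk"].isna().any():
        bad = genes.loc[genes["ct_hk"].isna(), ["sample", "replicate"]].drop_duplicates()
        raise DataError(
            "missing housekeeping Ct for sample/replicate pairs: "
            + ", ".join(f"{s}/{r}" for s, r in bad.itertuples(index=False))
        )
    genes["delta_ct"] = genes["ct"] - genes["ct_hk"]

    ref = genes[genes["sample"] == table.reference_sample]
    ref_mean = ref.groupby("gene")["delta_ct"].mean().rename("ref_delta_ct")
    genes = genes.join(ref_mean, on="gene")
    if genes["ref_delta_ct"].isna().any():
        bad = sorted(genes.loc[genes["ref_delta_ct"].isna(), "gene"].unique())
        raise DataError(f"reference sample has no ΔCt for genes: {bad}")
    genes["delta_delta_ct"] = genes["delta_ct"] - genes["ref_delta_ct"]
    genes["rq"] = np.exp2(-genes["delta_delta_ct"])

    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    summary = (
        genes.groupby(["sample", "gene"])
        .agg(
            n=("rq", "size"),
            mean_delta_delta_ct=("delta_delta_ct", "mean"),
            sem_delta_delta_ct=("delta_delta_ct", sem),
            mean_rq=("rq", "mean"),
            sem_rq=("rq", sem),
        )
        .reset_index()
    )
    # RQ of the mean ΔΔCt (exactly 1 for the reference sample)
    summary["rq_of_mean_ddct"] = np.exp2(-summary["mean_delta_delta_ct"])
    cols = ["sample", "gene", "replicate", "ct", "delta_ct", "delta_delta_ct", "rq"]
    return {"replicates": genes[cols].reset_index(drop=True), "summary": summary}
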