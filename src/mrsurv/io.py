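"""Readers and writers for the three delimited study inputs.

* weight file: tab-delimited, header
  ``snp_id effect_allele other_allele beta se pvalue eaf``;
* dosage file: tab-delimited, first column ``sample_id``, one column per
  SNP, missing dosages encoded ``NA``;
* cohort file: tab-delimited, fixed column names (sample_id, sex, age,
  pc1..pc10, chip, exposure_*, followup_years, event, prevalent,
  lipid_med, plus the observational adjustment columns).

Writers format floats with repr-stable precision so that a fixed seed
yields byte-identical fixtures across runs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .grs import GenotypePanel

__all__ = [
    "write_weights",
    "read_weights",
    "write_dosages",
    "read_dosages",
    "write_cohort",
    "read_cohort",
    "write_fixture",
    "read_fixture",
]

_FLOAT_FMT = "%.10g"


def write_weights(weights: pd.DataFrame, path):
    cols = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "eaf"]
    weights[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "eaf"]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"weight file missing columns: {sorted(missing)}")
    return df


def write_dosages(panel: GenotypePanel, path):
    df = panel.to_frame().reset_index()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_dosages(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise ValueError("dosage file must start with a sample_id column")
    sample_ids = pd.Index(df["sample_id"].astype(str), name="sample_id")
    snp_ids = pd.Index(df.columns[1:], name="snp_id")
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypePanel(dosages=dosages, sample_ids=sample_ids, snp_ids=snp_ids)


def write_cohort(cohort: pd.DataFrame, path):
    if "sample_id" not in cohort.columns:
        raise ValueError("cohort table needs a sample_id column")
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("sample_id", "followup_years", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort file missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_fixture(panel, cohort, weights, outdir):
    """Write the three study inputs under ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "weights": os.path.join(outdir, "weights.tsv"),
        "dosages": os.path.join(outdir, "dosages.tsv"),
        "cohort": os.path.join(outdir, "cohort.tsv"),
    }
    write_weights(weights, paths["weights"])
    write_dosages(panel, paths["dosages"])
    write_cohort(cohort, paths["cohort"])
    return paths


def read_fixture(indir):
    """Read back a fixture directory written by :func:`write_fixture`."""
    return (
        read_dosages(os.path.join(indir, "dosages.tsv")),
        read_cohort(os.path.join(indir, "cohort.tsv")),
        read_weights(os.path.join(indir, "weights.tsv")),
    )
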