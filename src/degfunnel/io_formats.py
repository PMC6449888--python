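"""File formats and in-memory containers for the pipeline.

The probe-level dialect is a GenomeStudio-style tab-separated export:
``ProbeID``, ``GeneSymbol``, ``IsNegativeControl``, then one
``<sample>.AVG_Signal`` / ``<sample>.Detection_Pval`` column pair per
sample.  All writers emit tab-separated text with 6-significant-digit
numeric formatting so that write→read round-trips are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

NUM_FMT = "%.6g"


class FormatError(ValueError):
    """Raised on malformed input files, with row/column context."""


def _fmt(x: float) -> str:
    return NUM_FMT % x


# ---------------------------------------------------------------------------
# Sample sheet


class SampleSheet:
    """Paired sample metadata: one 0W and one 12W sample per patient.

    Trait codes (0W → 1, 12W → 2) are derived from the timepoint, never
    stored independently.
    """

    TIMEPOINTS = ("0W", "12W")

    def __init__(self, table: pd.DataFrame):
        required = {"sample_id", "patient_id", "timepoint"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        table = table[["sample_id", "patient_id", "timepoint"]].astype(str).reset_index(drop=True)
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        bad_tp = sorted(set(table["timepoint"]) - set(self.TIMEPOINTS))
        if bad_tp:
            raise FormatError(f"unknown timepoints {bad_tp}; expected {self.TIMEPOINTS}")
        for patient, grp in table.groupby("patient_id", sort=False):
            tps = sorted(grp["timepoint"])
            if tps != ["0W", "12W"]:
                raise FormatError(
                    f"patient {patient!r} must have exactly one 0W and one 12W sample, "
                    f"found timepoints {list(grp['timepoint'])}"
                )
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def trait_codes(self, code_map: dict[str, int] | None = None) -> pd.Series:
        code_map = code_map or {"0W": 1, "12W": 2}
        return pd.Series(
            [code_map[t] for t in self.table["timepoint"]],
            index=self.table["sample_id"].tolist(),
            name="trait",
        )

    def samples_at(self, timepoint: str) -> list[str]:
        sel = self.table[self.table["timepoint"] == timepoint]
        return sel["sample_id"].tolist()

    def pairs(self) -> list[tuple[str, str, str]]:
        """(patient, 0W sample, 12W sample) triples in patient order."""
        out = []
        for patient in self.patients:
            grp = self.table[self.table["patient_id"] == patient]
            s0 = grp.loc[grp["timepoint"] == "0W", "sample_id"].iloc[0]
            s1 = grp.loc[grp["timepoint"] == "12W", "sample_id"].iloc[0]
            out.append((patient, s0, s1))
        return out

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(self.table[self.table["sample_id"].isin(keep)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.table.equals(other.table)

    def __len__(self) -> int:
        return len(self.table)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe matrix


@dataclass
class ProbeMatrix:
    """Probe × sample raw intensities with detection p-values.

    ``intensity`` and ``detection_p`` are probe × sample DataFrames sharing
    index (probe ids) and columns (sample ids); ``gene_symbol`` is empty for
    negative-control probes.
    """

    gene_symbol: pd.Series
    is_negative_control: pd.Series
    intensity: pd.DataFrame
    detection_p: pd.DataFrame
    steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.intensity.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if not self.detection_p.index.equals(idx) or not self.detection_p.columns.equals(
            self.intensity.columns
        ):
            raise FormatError("intensity and detection_p must share index and columns")
        if not self.gene_symbol.index.equals(idx) or not self.is_negative_control.index.equals(idx):
            raise FormatError("gene_symbol / is_negative_control must be indexed by probe id")
        dp = self.detection_p.to_numpy()
        if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
            bad = self.detection_p[(self.detection_p < 0) | (self.detection_p > 1)].stack()
            loc = bad.index[0]
            raise FormatError(
                f"detection p outside [0, 1] at probe {loc[0]!r}, sample {loc[1]!r}: {bad.iloc[0]}"
            )
        nc = self.is_negative_control.astype(bool)
        bad_nc = self.gene_symbol[nc][self.gene_symbol[nc] != ""]
        if len(bad_nc):
            raise FormatError(
                f"negative-control probes must have empty gene symbol: {bad_nc.index[:5].tolist()}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.intensity.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.intensity.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self.intensity.shape[0]

    def subset_probes(self, probe_ids: Iterable[str], step: str | None = None) -> "ProbeMatrix":
        idx = pd.Index(probe_ids)
        return ProbeMatrix(
            gene_symbol=self.gene_symbol.loc[idx],
            is_negative_control=self.is_negative_control.loc[idx],
            intensity=self.intensity.loc[idx],
            detection_p=self.detection_p.loc[idx],
            steps=self.steps + ([step] if step else []),
        )

    def with_intensity(self, values: pd.DataFrame, step: str) -> "ProbeMatrix":
        return ProbeMatrix(
            gene_symbol=self.gene_symbol,
            is_negative_control=self.is_negative_control,
            intensity=values,
            detection_p=self.detection_p,
            steps=self.steps + [step],
        )


def read_probe_matrix(path: str | Path) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"ProbeID": str, "GeneSymbol": str})
    fixed = ["ProbeID", "GeneSymbol", "IsNegativeControl"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rest = [c for c in df.columns if c not in fixed]
    signal_samples = [c[: -len(".AVG_Signal")] for c in rest if c.endswith(".AVG_Signal")]
    pval_samples = [c[: -len(".Detection_Pval")] for c in rest if c.endswith(".Detection_Pval")]
    unknown = [c for c in rest if not (c.endswith(".AVG_Signal") or c.endswith(".Detection_Pval"))]
    if unknown:
        raise FormatError(f"{path}: unrecognized columns {unknown}")
    for s in signal_samples:
        if s not in pval_samples:
            raise FormatError(f"{path}: sample {s!r} has AVG_Signal but no Detection_Pval column")
    for s in pval_samples:
        if s not in signal_samples:
            raise FormatError(f"{path}: sample {s!r} has Detection_Pval but no AVG_Signal column")
    if not signal_samples:
        raise FormatError(f"{path}: no sample columns found")
    if df["ProbeID"].duplicated().any():
        dups = df.loc[df["ProbeID"].duplicated(), "ProbeID"].tolist()
        raise FormatError(f"{path}: duplicate probe ids {dups[:5]}")
    idx = pd.Index(df["ProbeID"], name="ProbeID")
    gene_symbol = pd.Series(df["GeneSymbol"].fillna("").to_numpy(), index=idx, name="GeneSymbol")
    is_nc = pd.Series(
        df["IsNegativeControl"].astype(int).astype(bool).to_numpy(), index=idx,
        name="IsNegativeControl",
    )
    intensity = pd.DataFrame(
        {s: df[f"{s}.AVG_Signal"].astype(float).to_numpy() for s in signal_samples}, index=idx
    )
    detection = pd.DataFrame(
        {s: df[f"{s}.Detection_Pval"].astype(float).to_numpy() for s in signal_samples}, index=idx
    )
    return ProbeMatrix(gene_symbol, is_nc, intensity, detection)


def write_probe_matrix(pm: ProbeMatrix, path: str | Path) -> None:
    cols = {
        "ProbeID": pm.intensity.index,
        "GeneSymbol": pm.gene_symbol.to_numpy(),
        "IsNegativeControl": pm.is_negative_control.astype(int).to_numpy(),
    }
    out = pd.DataFrame(cols)
    for s in pm.sample_ids:
        out[f"{s}.AVG_Signal"] = [_fmt(v) for v in pm.intensity[s]]
        out[f"{s}.Detection_Pval"] = [_fmt(v) for v in pm.detection_p[s]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Gene × sample log2 expression with paired sample metadata."""

    values: pd.DataFrame
    samples: SampleSheet
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene symbols: {dups[:5]}")
        if list(self.values.columns) != self.samples.sample_ids:
            raise FormatError("expression columns must match sample sheet order")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_genes(self, genes: Iterable[str], step: str | None = None) -> "ExpressionMatrix":
        idx = pd.Index(genes)
        return ExpressionMatrix(
            values=self.values.loc[idx],
            samples=self.samples,
            provenance=self.provenance + ([step] if step else []),
        )

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    out = em.values.copy()
    out = out.map(_fmt)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path, samples: SampleSheet) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in samples.sample_ids if s not in df.columns]
    if missing:
        raise FormatError(f"{path}: expression file missing samples {missing}")
    return ExpressionMatrix(df[samples.sample_ids].astype(float), samples, provenance=[{"step": "read", "path": str(path)}])


# ---------------------------------------------------------------------------
# Gene sets (GMT)


class GeneSetCollection:
    """Ordered collection of named gene sets (flat, GMT-backed)."""

    def __init__(self, sets: dict[str, set[str]], names: dict[str, str] | None = None):
        for sid, members in sets.items():
            if not members:
                raise FormatError(f"gene set {sid!r} is empty")
        self.sets: dict[str, set[str]] = dict(sets)
        self.names: dict[str, str] = names or {sid: sid for sid in sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, sid: str) -> set[str]:
        return self.sets[sid]

    def items(self):
        return self.sets.items()

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with a background universe, dropping empties."""
        kept = {sid: members & universe for sid, members in self.sets.items()}
        kept = {sid: m for sid, m in kept.items() if m}
        return GeneSetCollection(kept, {sid: self.names[sid] for sid in kept})


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}")
            sid, desc, *genes = parts
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = set(g for g in genes if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {sid!r} has no genes")
            sets[sid] = members
            names[sid] = desc
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, members in collection.items():
            fh.write("\t".join([sid, collection.names.get(sid, sid), *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Clinical table


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "PASI_0", "PASI_12"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise FormatError(f"{path}: duplicate patients {dups}")
    df = df.set_index("patient_id")
    df["PASI_0"] = df["PASI_0"].astype(float)
    df["PASI_12"] = df["PASI_12"].astype(float)
    return df


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
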