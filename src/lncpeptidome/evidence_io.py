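"""MaxQuant-style peptide evidence tables and sample annotations.

The evidence table is a peptide-by-sample intensity matrix plus a
peptide -> database-entry mapping.  MaxQuant writes 0 for non-quantified
cells; on ingest every 0 becomes NaN (missing) so that zeros never pollute
medians or fold changes.  Intensities stay on the raw linear scale here;
log2 happens only in the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV")
CONDITIONS = ("normal", "cancer", "none")


class SchemaError(ValueError):
    """Evidence or annotation file violates the expected schema."""


@dataclass(frozen=True)
class SampleAnnotation:
    """One sample: context (tissue / cell line / cohort), condition, stage."""

    sample_id: str
    context: str
    condition: str = "none"
    stage: str = "NA"
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}"
            )
        if self.stage != "NA" and self.stage not in STAGES:
            raise SchemaError(f"sample {self.sample_id!r}: unknown stage {self.stage!r}")
        if self.stage != "NA" and self.condition != "cancer":
            raise SchemaError(
                f"sample {self.sample_id!r}: stage given for non-cancer sample"
            )


@dataclass
class PeptideEvidenceTable:
    """Peptide evidence: mapping Series + intensity DataFrame (NaN = missing).

    ``mapping`` maps peptide sequence -> tuple of database entry ids;
    ``intensity`` is indexed by peptide sequence with one column per sample.
    """

    mapping: dict[str, tuple[str, ...]]
    intensity: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensity.index.has_duplicates:
            dups = self.intensity.index[self.intensity.index.duplicated()]
            raise SchemaError(f"duplicate peptide rows: {sorted(set(dups))}")
        vals = self.intensity.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise SchemaError("negative intensity")
        # zero-coded missingness: recode on construction
        self.intensity = self.intensity.mask(self.intensity == 0, np.nan)
        missing = set(self.intensity.index) - set(self.mapping)
        if missing:
            raise SchemaError(f"peptides without mapping: {sorted(missing)[:5]}")

    @property
    def peptides(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def validate_against(self, annotation: list[SampleAnnotation]) -> None:
        known = {a.sample_id for a in annotation}
        unknown = [s for s in self.samples if s not in known]
        if unknown:
            raise SchemaError(f"samples not in annotation: {unknown}")


# ---------------------------------------------------------------------------
# readers / writers

_MAXQUANT_PREFIX = "Intensity "


def read_evidence(
    path, dialect: str = "maxquant", intensity_prefix: str = _MAXQUANT_PREFIX
) -> PeptideEvidenceTable:
    """Read a peptide evidence TSV.

    ``maxquant`` dialect: wide table with columns ``Sequence``, ``Proteins``
    (semicolon-separated) and one ``Intensity <sample>`` column per sample.
    ``plain`` dialect: long table ``peptide, entry_ids, sample, intensity``.
    """
    if dialect not in ("maxquant", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if dialect == "maxquant":
        for col in ("Sequence", "Proteins"):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        icols = [c for c in df.columns if c.startswith(intensity_prefix)]
        if not icols:
            raise SchemaError(f"no intensity columns with prefix {intensity_prefix!r}")
        if df["Sequence"].duplicated().any():
            raise SchemaError(
                f"duplicate peptide rows: {df['Sequence'][df['Sequence'].duplicated()].tolist()}"
            )
        mapping = {
            row.Sequence: tuple(str(row.Proteins).split(";"))
            for row in df.itertuples()
        }
        intensity = df.set_index("Sequence")[icols].astype(float)
        intensity.columns = [c[len(intensity_prefix):] for c in icols]
        intensity.index.name = "peptide"
        return PeptideEvidenceTable(mapping=mapping, intensity=intensity)
    # plain long format
    for col in ("peptide", "entry_ids", "sample", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if df.duplicated(subset=["peptide", "sample"]).any():
        raise SchemaError("duplicate (peptide, sample) rows")
    mapping = {
        pep: tuple(str(eids).split(";"))
        for pep, eids in df.drop_duplicates("peptide")[["peptide", "entry_ids"]].itertuples(
            index=False
        )
    }
    intensity = df.pivot(index="peptide", columns="sample", values="intensity").astype(
        float
    )
    return PeptideEvidenceTable(mapping=mapping, intensity=intensity)


def write_evidence(table: PeptideEvidenceTable, path, dialect: str = "maxquant") -> None:
    """Write an evidence table; missing cells are written as 0 (MaxQuant) or
    omitted (plain long format)."""
    if dialect == "maxquant":
        df = table.intensity.fillna(0.0).copy()
        df.columns = [_MAXQUANT_PREFIX + c for c in df.columns]
        df.insert(0, "Proteins", [";".join(table.mapping[p]) for p in df.index])
        df.insert(0, "Sequence", df.index)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "plain":
        long = (
            table.intensity.stack()
            .rename("intensity")
            .reset_index()
            .rename(columns={"level_1": "sample"})
        )
        long.insert(1, "entry_ids", [";".join(table.mapping[p]) for p in long["peptide"]])
        long.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


_STAGE_ALIASES = {
    "i": "I", "ii": "II", "iii": "III", "iv": "IV",
    "stage i": "I", "stage ii": "II", "stage iii": "III", "stage iv": "IV",
    "na": "NA", "": "NA", "nan": "NA",
}


def _parse_stage(token: str) -> str:
    key = str(token).strip().lower()
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    raise SchemaError(f"unknown stage token {token!r}")


def read_annotation(path) -> list[SampleAnnotation]:
    """Read the sample annotation TSV (sample_id, context, condition, stage[, pair_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "context"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise SchemaError(f"duplicate sample_id: {dups}")
    out = []
    for row in df.itertuples():
        out.append(
            SampleAnnotation(
                sample_id=row.sample_id,
                context=row.context,
                condition=getattr(row, "condition", "") or "none",
                stage=_parse_stage(getattr(row, "stage", "NA")),
                pair_id=getattr(row, "pair_id", "") or None,
            )
        )
    return out


def write_annotation(annotation: list[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "context": a.context,
                "condition": a.condition,
                "stage": a.stage,
                "pair_id": a.pair_id or "",
            }
            for a in annotation
        ]
    ).to_csv(path, sep="\t", index=False)
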