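"""Synthetic transcripts, proteome and peptide-evidence cohorts.

The generator plants a known ground truth through the whole pipeline:
transcripts carry one open reading frame whose tryptic peptides are absent
from the synthetic proteome (except a configurable decoy fraction copied
into proteome entries to exercise the novelty filter); peptide evidence is
drawn from a log-normal intensity model with additive effects on the log2
scale, zero/NaN-coded missingness, planted context-specific / shared /
ubiquitous / universally-expressed polypeptides, planted cancer-vs-normal
fold changes and monotone stage trends.

Defaults mirror the study design this package targets: 14 tissues and 11
cell lines with a handful of ubiquitous polypeptides of which ~5 are
universal, and a colon-cancer cohort of 92 tumors (stages I-IV) against 30
normals.  Peptides within one group share the group's sample-level signal
plus small peptide-level noise (0.1 x log2_sd), so the within-context %CV
is low, as observed for real lncRNA polypeptide evidence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .evidence_io import PeptideEvidenceTable, SampleAnnotation
from .lncdb import (
    NucleotideTranscript,
    ReferenceProteome,
    three_frame_translate,
)

TISSUES_14 = (
    "heart", "frontal_cortex", "urinary_bladder", "testis", "prostate",
    "liver", "adrenal_gland", "ovary", "spinal_cord", "colon", "lung",
    "pancreas", "kidney", "esophagus",
)
CELLLINES_11 = (
    "A549", "GAMG", "HEK293", "HeLa", "HepG2", "Jurkat", "K562",
    "LnCap", "MCF7", "RKO", "U2OS",
)

# residues used for planted peptides: no K/R/P (cleavage control), no I
# (so I/L collapse cannot create accidental proteome matches), no C/M/W
# oddities needed -- a 15-letter working alphabet
_PEP_ALPHABET = "ADEFGHLMNQSTVWY"
_FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per amino acid for deterministic reverse translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    seed: int = 0
    n_tissues: int = 14
    n_celllines: int = 11
    samples_per_context: int = 3
    n_groups: int = 60
    fraction_specific: float = 0.45
    fraction_ubiquitous: float = 0.12   # ~7 of 60, as in the tissue panel
    fraction_uexp: float = 0.08         # ~5 of 60 universal, subset of ubiquitous
    peptides_per_group: int = 4         # ~2606 peptides / 665 polypeptides
    log2_mean: float = 25.0
    log2_sd: float = 1.0
    dropout_prob: float = 0.1
    dropout_model: str = "mcar"         # or "censored" (logistic in log2 intensity)
    n_cancer: int = 92
    n_normal: int = 30
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    stage_slope: float = 0.5            # log2 per stage step for DE groups
    decoy_fraction: float = 0.0
    n_proteome: int = 20
    proteome_len: int = 300
    min_peptide_len: int = 7
    max_peptide_len: int = 12

    def __post_init__(self) -> None:
        if self.peptides_per_group < 2:
            raise ValueError("peptides_per_group must be >= 2 (detection rule)")
        if self.fraction_uexp > self.fraction_ubiquitous:
            raise ValueError("fraction_uexp must not exceed fraction_ubiquitous")
        if self.fraction_specific + self.fraction_ubiquitous > 1:
            raise ValueError("class fractions must sum to at most 1")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")


@dataclass
class GroupTruth:
    group_id: str
    transcript_id: str
    entry_id: str
    planted_class: str                  # specific | shared | ubiquitous | uexp
    tissue_contexts: list[str]
    cellline_contexts: list[str]
    peptides: list[str]
    orf: str
    de_status: bool = False
    log2fc: float = 0.0
    stage_trend: bool = False


@dataclass
class GroundTruth:
    groups: dict[str, GroupTruth]
    decoy_peptides: list[str]
    tissues: list[str]
    celllines: list[str]

    @property
    def peptide_to_group(self) -> dict[str, str]:
        return {p: g.group_id for g in self.groups.values() for p in g.peptides}

    def ids_of_class(self, cls: str) -> set[str]:
        return {g.group_id for g in self.groups.values() if g.planted_class == cls}

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": {k: asdict(v) for k, v in self.groups.items()},
                "decoy_peptides": self.decoy_peptides,
                "tissues": self.tissues,
                "celllines": self.celllines,
            },
            indent=1,
            sort_keys=True,
        )


def _context_names(base: tuple[str, ...], n: int, prefix: str) -> list[str]:
    if n <= len(base):
        return list(base[:n])
    return list(base) + [f"{prefix}{i}" for i in range(len(base), n)]


def _random_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(_PEP_ALPHABET), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[list[NucleotideTranscript], ReferenceProteome, GroundTruth]:
    """Generate transcripts with planted ORFs, a decoy-spiked proteome and
    the ground-truth manifest.  Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tissues = _context_names(TISSUES_14, config.n_tissues, "tissue")
    celllines = _context_names(CELLLINES_11, config.n_celllines, "cellline")

    n_spec = int(round(config.fraction_specific * config.n_groups))
    n_uexp = int(round(config.fraction_uexp * config.n_groups))
    n_ubiq = int(round(config.fraction_ubiquitous * config.n_groups))
    classes = (
        ["specific"] * n_spec
        + ["uexp"] * n_uexp
        + ["ubiquitous"] * (n_ubiq - n_uexp)
        + ["shared"] * (config.n_groups - n_spec - n_ubiq)
    )

    seen_peptides: set[str] = set()
    groups: dict[str, GroupTruth] = {}
    transcripts: list[NucleotideTranscript] = []
    biotype_pool = ("lincRNA", "antisense", "processed_transcript",
                    "sense_intronic", "sense_overlapping")
    # biotype mix of the reported tissue peptidome: linc 49%, antisense 37%,
    # processed 9%, sense-intronic 3%, sense-overlapping 2%
    biotype_probs = (0.49, 0.37, 0.09, 0.03, 0.02)

    for gi, cls in enumerate(classes):
        tx_id = f"TX{gi:04d}"
        peps: list[str] = []
        while len(peps) < config.peptides_per_group:
            pep = _random_peptide(rng, config.min_peptide_len, config.max_peptide_len)
            if pep not in seen_peptides:
                seen_peptides.add(pep)
                peps.append(pep)
        orf = "".join(peps)
        nt = "TAA" + "".join(_CODON[aa] for aa in orf) + "TAA"
        biotype = str(rng.choice(biotype_pool, p=biotype_probs))
        transcripts.append(
            NucleotideTranscript(transcript_id=tx_id, sequence=nt, biotype=biotype)
        )
        if cls == "specific":
            t_ctx = [tissues[gi % len(tissues)]]
            c_ctx = [celllines[gi % len(celllines)]]
        elif cls == "uexp":
            t_ctx, c_ctx = list(tissues), list(celllines)
        elif cls == "ubiquitous":
            # ubiquitous in tissues, strict subset of cell lines
            k = int(rng.integers(1, len(celllines)))
            c_ctx = sorted(rng.choice(celllines, size=k, replace=False))
            t_ctx = list(tissues)
        else:  # shared
            kt = int(rng.integers(2, len(tissues)))
            kc = int(rng.integers(1, len(celllines)))
            t_ctx = sorted(rng.choice(tissues, size=kt, replace=False))
            c_ctx = sorted(rng.choice(celllines, size=kc, replace=False))
        groups[tx_id] = GroupTruth(
            group_id=tx_id,
            transcript_id=tx_id,
            entry_id="",  # filled below from the actual translation
            planted_class=cls,
            tissue_contexts=t_ctx,
            cellline_contexts=c_ctx,
            peptides=peps,
            orf=orf,
        )

    for tx in transcripts:
        gt = groups[tx.transcript_id]
        for orf in three_frame_translate(tx, min_orf_len=1):
            if orf.sequence == gt.orf:
                gt.entry_id = orf.entry_id
                break
        if not gt.entry_id:
            raise RuntimeError("planted ORF not recovered by translation")

    # proteome: random entries, then spike a decoy fraction of planted peptides
    proteome_entries: dict[str, str] = {}
    for pi in range(config.n_proteome):
        while True:
            seq = "".join(rng.choice(list(_FULL_ALPHABET), size=config.proteome_len))
            collapsed = seq.replace("I", "L")
            if not any(p.replace("I", "L") in collapsed for p in seen_peptides):
                break
        proteome_entries[f"PROT{pi:03d}"] = seq

    all_peps = sorted(seen_peptides)
    n_decoy = int(round(config.decoy_fraction * len(all_peps)))
    decoys = sorted(rng.choice(all_peps, size=n_decoy, replace=False)) if n_decoy else []
    pids = list(proteome_entries)
    for pep in decoys:
        # appended, never inserted: a mid-sequence insertion could split a
        # decoy placed earlier in the same entry
        pid = pids[int(rng.integers(len(pids)))]
        proteome_entries[pid] = proteome_entries[pid] + pep

    # DE / stage assignment for the cancer cohort, uexp groups first: the
    # universal polypeptides are the cohort's biomarker candidates
    n_de = int(round(config.de_fraction * config.n_groups))
    ordered = sorted(groups, key=lambda g: (groups[g].planted_class != "uexp", g))
    for gid in ordered[:n_de]:
        groups[gid].de_status = True
        groups[gid].log2fc = config.de_log2fc
        groups[gid].stage_trend = True

    truth = GroundTruth(
        groups=groups,
        decoy_peptides=list(decoys),
        tissues=tissues,
        celllines=celllines,
    )
    return transcripts, ReferenceProteome(entries=proteome_entries), truth


# ---------------------------------------------------------------------------
# evidence simulation


@dataclass
class SimulatedCohort:
    """Evidence tables per panel plus the planted per-sample group signal."""

    evidence: dict[str, PeptideEvidenceTable]
    annotation: list[SampleAnnotation]
    planted_abundance: dict[str, pd.DataFrame] = field(default_factory=dict)


def _apply_dropout(
    intensity: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    if config.dropout_prob == 0:
        return intensity
    vals = intensity.to_numpy()
    present = ~np.isnan(vals)
    if config.dropout_model == "mcar":
        drop = rng.random(vals.shape) < config.dropout_prob
    elif config.dropout_model == "censored":
        # logistic in log2 intensity, centred so the marginal rate matches
        # dropout_prob at the median intensity
        with np.errstate(invalid="ignore"):
            log2 = np.log2(vals)
        centre = np.nanmedian(log2)
        logit0 = np.log(config.dropout_prob / (1 - config.dropout_prob))
        prob = 1.0 / (1.0 + np.exp(-(logit0 - (log2 - centre))))
        drop = rng.random(vals.shape) < np.nan_to_num(prob)
    else:
        raise ValueError(f"unknown dropout_model {config.dropout_model!r}")
    out = vals.copy()
    out[present & drop] = np.nan
    return pd.DataFrame(out, index=intensity.index, columns=intensity.columns)


def _panel_evidence(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
    samples: list[str],
    sample_context: dict[str, str],
    group_present: dict[str, set[str]],
    sample_shift: dict[str, float] | None = None,
    effect_context: dict[str, str] | None = None,
) -> tuple[PeptideEvidenceTable, pd.DataFrame]:
    """Build one panel: group signal per sample, peptide-level observations.

    ``effect_context`` optionally decouples the biological context effect
    from the presence/annotation context (a tumor cohort and its normal
    counterpart share one tissue effect).
    """
    sample_shift = sample_shift or {}
    effect_context = effect_context or sample_context
    pep_noise_sd = 0.1 * config.log2_sd
    gids = sorted(truth.groups)
    planted = pd.DataFrame(np.nan, index=gids, columns=samples, dtype=float)
    rows: dict[str, dict[str, float]] = {}
    mapping: dict[str, tuple[str, ...]] = {}
    for gid in gids:
        g = truth.groups[gid]
        base = float(rng.normal(0.0, 1.0))
        ctx_eff = {
            ctx: float(rng.normal(0.0, 1.0))
            for ctx in sorted({effect_context[s] for s in samples})
        }
        for pep in g.peptides:
            mapping[pep] = (g.entry_id,)
            rows.setdefault(pep, {})
        for s in samples:
            ctx = sample_context[s]
            if ctx not in group_present[gid]:
                continue
            mu = (
                config.log2_mean
                + base
                + ctx_eff[effect_context[s]]
                + sample_shift.get(s, 0.0) * (1.0 if g.de_status else 0.0)
                + float(rng.normal(0.0, config.log2_sd))
            )
            planted.loc[gid, s] = 2.0 ** mu
            for pep in g.peptides:
                rows[pep][s] = 2.0 ** (mu + float(rng.normal(0.0, pep_noise_sd)))
    intensity = pd.DataFrame(rows).T.reindex(columns=samples)
    intensity.index.name = "peptide"
    intensity = _apply_dropout(intensity, config, rng)
    return PeptideEvidenceTable(mapping=mapping, intensity=intensity), planted


def simulate_evidence(config: SimConfig, truth: GroundTruth) -> SimulatedCohort:
    """Simulate tissue, cell-line, cancer-cohort and plasma evidence panels.

    Peptide intensity is 2^(log2_mean + group effect + context effect +
    sample noise + peptide noise); context-restricted groups are missing by
    design outside their contexts; colon-cohort DE groups carry the planted
    fold change plus a monotone stage trend.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    annotation: list[SampleAnnotation] = []
    evidence: dict[str, PeptideEvidenceTable] = {}
    planted: dict[str, pd.DataFrame] = {}

    # --- tissue and cell-line panels
    for panel, contexts, attr in (
        ("tissue", truth.tissues, "tissue_contexts"),
        ("cellline", truth.celllines, "cellline_contexts"),
    ):
        samples, ctx_of = [], {}
        for ctx in contexts:
            for i in range(config.samples_per_context):
                sid = f"{ctx}_s{i + 1}"
                samples.append(sid)
                ctx_of[sid] = ctx
                annotation.append(SampleAnnotation(sample_id=sid, context=ctx))
        present = {
            gid: set(getattr(g, attr)) for gid, g in truth.groups.items()
        }
        evidence[panel], planted[panel] = _panel_evidence(
            truth, config, rng, samples, ctx_of, present
        )

    # --- colon cancer cohort: stages cycle I..IV over the tumors
    stages = [("I", "II", "III", "IV")[i % 4] for i in range(config.n_cancer)]
    samples, ctx_of, shift = [], {}, {}
    for i in range(config.n_cancer):
        sid = f"COAD_{i + 1:03d}"
        samples.append(sid)
        ctx_of[sid] = "COAD"
        stage_idx = ("I", "II", "III", "IV").index(stages[i])
        shift[sid] = config.de_log2fc + config.stage_slope * stage_idx
        annotation.append(
            SampleAnnotation(sid, context="COAD", condition="cancer", stage=stages[i])
        )
    for i in range(config.n_normal):
        sid = f"NC_{i + 1:03d}"
        samples.append(sid)
        ctx_of[sid] = "normal_colon"
        annotation.append(SampleAnnotation(sid, context="normal_colon", condition="normal"))
    present = {gid: {"COAD", "normal_colon"} for gid in truth.groups}
    evidence["cancer"], planted["cancer"] = _panel_evidence(
        truth, config, rng, samples, ctx_of, present, sample_shift=shift,
        effect_context={s: "colon" for s in samples},
    )

    # --- plasma panel: the universal polypeptides circulate
    plasma_samples = ["PL_H1", "PL_H2", "PL_C1", "PL_C2"]
    ctx_of = {s: "plasma" for s in plasma_samples}
    for s in plasma_samples:
        annotation.append(
            SampleAnnotation(
                s, context="plasma",
                condition="cancer" if s.startswith("PL_C") else "normal",
            )
        )
    present = {
        gid: ({"plasma"} if g.planted_class in ("uexp", "ubiquitous") else set())
        for gid, g in truth.groups.items()
    }
    evidence["plasma"], planted["plasma"] = _panel_evidence(
        truth, config, rng, plasma_samples, ctx_of, present
    )

    return SimulatedCohort(
        evidence=evidence, annotation=annotation, planted_abundance=planted
    )


# ---------------------------------------------------------------------------
# matrix-level simulators for statistical calibration studies


def simulate_de_matrix(
    n_rows: int,
    n1: int,
    n2: int,
    de_fraction: float = 0.0,
    log2fc: float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Gaussian log2 matrix for two-group tests with planted effects.

    Returns (matrix, sample labels 'g1'/'g2', boolean planted-effect flags);
    the first round(de_fraction * n_rows) rows carry +log2fc in group 2.
    """
    rng = np.random.default_rng(seed)
    cols = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    labels = pd.Series(["g1"] * n1 + ["g2"] * n2, index=cols)
    x = rng.normal(0.0, sd, size=(n_rows, n1 + n2))
    n_de = int(round(de_fraction * n_rows))
    x[:n_de, n1:] += log2fc
    flags = np.zeros(n_rows, dtype=bool)
    flags[:n_de] = True
    matrix = pd.DataFrame(x, index=[f"row{i}" for i in range(n_rows)], columns=cols)
    return matrix, labels, flags


def simulate_stage_matrix(
    n_rows: int,
    n_per_stage: int = 5,
    trend_fraction: float = 0.0,
    slope: float = 0.5,
    sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Gaussian log2 matrix over stages I-IV with planted monotone trends.

    Trend rows gain slope * (stage index) on the log2 scale.
    """
    rng = np.random.default_rng(seed)
    stages = ("I", "II", "III", "IV")
    cols, labs = [], []
    for s in stages:
        for i in range(n_per_stage):
            cols.append(f"{s}_{i}")
            labs.append(s)
    labels = pd.Series(labs, index=cols)
    x = rng.normal(0.0, sd, size=(n_rows, len(cols)))
    n_trend = int(round(trend_fraction * n_rows))
    for j, s in enumerate(labs):
        x[:n_trend, j] += slope * stages.index(s)
    flags = np.zeros(n_rows, dtype=bool)
    flags[:n_trend] = True
    matrix = pd.DataFrame(x, index=[f"row{i}" for i in range(n_rows)], columns=cols)
    return matrix, labels, flags
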