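import numpy as np
import pandas as pd
import pytest

from lncpeptidome import lncdb
from lncpeptidome.evidence_io import PeptideEvidenceTable
from lncpeptidome.synthetic import SimConfig, simulate_evidence, simulate_transcriptome


@pytest.fixture
def make_cohort():
    """Factory: simulate a cohort and return everything the pipeline needs."""

    def _make(**overrides):
        defaults = dict(
            seed=11, n_groups=30, samples_per_context=2, n_cancer=16, n_normal=8
        )
        defaults.update(overrides)
        cfg = SimConfig(**defaults)
        transcripts, proteome, truth = simulate_transcriptome(cfg)
        cohort = simulate_evidence(cfg, truth)
        segments = {
            orf.entry_id: orf.sequence
            for t in transcripts
            for orf in lncdb.three_frame_translate(t, min_orf_len=8)
        }
        return cfg, transcripts, proteome, truth, cohort, segments

    return _make


def make_evidence(mapping: dict, intensities: dict, samples: list[str]) -> PeptideEvidenceTable:
    """Small hand-built evidence table; intensities: peptide -> list per sample."""
    df = pd.DataFrame(
        {s: {p: intensities[p][i] for p in mapping} for i, s in enumerate(samples)},
        dtype=float,
    )
    df.index.name = "peptide"
    return PeptideEvidenceTable(
        mapping={p: tuple(v) for p, v in mapping.items()}, intensity=df
    )


def lnc_entry(tx: str) -> str:
    return f"lncpep|{tx}|F0|S0"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
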