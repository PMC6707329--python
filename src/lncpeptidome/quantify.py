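"""Polypeptide grouping and label-free quantification.

Peptides observed for lncRNA database entries are grouped at the transcript
level: transcripts whose observed peptide sets are identical, or where one
set is contained in another, are merged into one reported polypeptide group
(subsumption grouping, as protein-inference tools do).  A peptide that maps
to two groups that cannot be merged is non-unique and is excluded from both
groups' unique peptide lists.

A group is reported only if it carries at least two non-overlapping unique
peptides; its per-sample abundance is the median of its unique peptides'
non-missing intensities in that sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evidence_io import PeptideEvidenceTable
from .lncdb import LNC_PREFIX


@dataclass(frozen=True)
class PeptideOccurrence:
    """One candidate placement of a peptide on a group's representative sequence."""

    peptide_sequence: str
    group_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.peptide_sequence):
            raise ValueError("interval length must equal peptide length")


@dataclass
class PolypeptideGroup:
    """One reported lncRNA polypeptide."""

    group_id: str
    member_transcript_ids: list[str]
    peptides: list[str]
    unique_peptides: list[str] = field(default_factory=list)
    occurrences: list[PeptideOccurrence] = field(default_factory=list)
    nonoverlap_count: int = 0
    representative_entry: str | None = None
    abundance: dict[str, float] = field(default_factory=dict)


def transcript_of_entry(entry_id: str) -> str:
    """``lncpep|TX1|F0|S2`` -> ``TX1``."""
    parts = entry_id.split("|")
    if parts[0] != LNC_PREFIX or len(parts) < 2:
        raise ValueError(f"not an lncRNA database entry: {entry_id!r}")
    return parts[1]


def group_shared_peptides(evidence: PeptideEvidenceTable) -> list[PolypeptideGroup]:
    """Merge transcripts by peptide-set subsumption; flag non-unique peptides.

    Only peptides mapped to the lncRNA namespace participate; peptides also
    mapped to a canonical proteome entry are ignored here (they fail the
    novelty criterion upstream).  Output is invariant to input order: groups
    are built from largest peptide set to smallest, ties broken by transcript
    id, and a subset transcript joins the group with the largest set.
    """
    tx_peps: dict[str, set[str]] = {}
    for pep, entries in evidence.mapping.items():
        lnc = [e for e in entries if e.startswith(LNC_PREFIX + "|")]
        if not lnc or len(lnc) != len(entries):
            continue
        for e in lnc:
            tx_peps.setdefault(transcript_of_entry(e), set()).add(pep)

    # largest-first so supersets found groups and subsets join them
    order = sorted(tx_peps, key=lambda t: (-len(tx_peps[t]), t))
    groups: list[dict] = []  # {'members': [...], 'peps': set}
    for tx in order:
        peps = tx_peps[tx]
        hosts = [g for g in groups if peps <= g["peps"]]
        if hosts:
            # deterministic: largest set wins; ties -> smallest leading member id
            host = sorted(hosts, key=lambda g: (-len(g["peps"]), g["members"][0]))[0]
            host["members"].append(tx)
        else:
            groups.append({"members": [tx], "peps": set(peps)})

    # peptides in more than one final group are non-unique
    pep_groups: dict[str, set[int]] = {}
    for gi, g in enumerate(groups):
        for pep in g["peps"]:
            pep_groups.setdefault(pep, set()).add(gi)
    out = []
    for g in groups:
        members = sorted(g["members"])
        unique = sorted(p for p in g["peps"] if len(pep_groups[p]) == 1)
        out.append(
            PolypeptideGroup(
                group_id=members[0],
                member_transcript_ids=members,
                peptides=sorted(g["peps"]),
                unique_peptides=unique,
            )
        )
    return sorted(out, key=lambda g: g.group_id)


def count_nonoverlapping_unique(occurrences: list[PeptideOccurrence]) -> int:
    """Maximum number of pairwise non-overlapping intervals, at most one
    interval per distinct peptide sequence.

    Exact maximization by depth-first search with a remaining-count bound;
    group peptide counts are small so this is cheap.  Intervals touching at a
    boundary do not overlap.
    """
    by_pep: dict[str, list[tuple[int, int]]] = {}
    for occ in occurrences:
        by_pep.setdefault(occ.peptide_sequence, []).append((occ.start, occ.end))
    choices = list(by_pep.values())
    best = 0

    def rec(i: int, chosen: list[tuple[int, int]]) -> None:
        nonlocal best
        if len(chosen) + len(choices) - i <= best:
            return
        if i == len(choices):
            best = max(best, len(chosen))
            return
        for s, e in choices[i]:
            if all(e <= s2 or e2 <= s for s2, e2 in chosen):
                chosen.append((s, e))
                rec(i + 1, chosen)
                chosen.pop()
        rec(i + 1, chosen)

    rec(0, [])
    return best


def locate_occurrences(
    peptide: str, representative_seq: str, group_id: str
) -> list[PeptideOccurrence]:
    """All placements of ``peptide`` on the representative sequence."""
    out = []
    start = representative_seq.find(peptide)
    while start != -1:
        out.append(PeptideOccurrence(peptide, group_id, start, start + len(peptide)))
        start = representative_seq.find(peptide, start + 1)
    return out


def median_lfq(
    group: PolypeptideGroup, evidence: PeptideEvidenceTable, sample_id: str
) -> float:
    """Median of the group's unique peptides' non-missing intensities in one
    sample (even counts: mean of the two central values); NaN if none."""
    vals = evidence.intensity.loc[
        [p for p in group.unique_peptides if p in evidence.intensity.index], sample_id
    ].dropna()
    return float(np.median(vals)) if len(vals) else math.nan


def peptide_cv(
    group: PolypeptideGroup, evidence: PeptideEvidenceTable, sample_set: list[str]
) -> float:
    """%CV (100 * sd / mean, sd with n-1 df) of the group's unique-peptide
    intensities pooled over the sample set; NaN below two values."""
    vals = (
        evidence.intensity.loc[
            [p for p in group.unique_peptides if p in evidence.intensity.index],
            list(sample_set),
        ]
        .to_numpy()
        .ravel()
    )
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        return math.nan
    return float(100.0 * np.std(vals, ddof=1) / np.mean(vals))


def cross_context_peptide_anova(
    values_by_context: dict[str, "np.ndarray"]
) -> tuple[float, float]:
    """One-way ANOVA (F, p) on log2 intensities of one peptide across contexts.

    Requires at least two contexts with at least two non-missing values each;
    otherwise returns (nan, nan).
    """
    arrays = []
    for vals in values_by_context.values():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) >= 2:
            arrays.append(np.log2(v))
    if len(arrays) < 2:
        return math.nan, math.nan
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def quantify_groups(
    evidence: PeptideEvidenceTable,
    segments: dict[str, str],
    min_nonoverlap: int = 2,
) -> tuple[pd.DataFrame, list[PolypeptideGroup]]:
    """Full quantification: group, apply the >= 2 non-overlapping unique
    peptide rule, and return the abundance matrix (groups x samples).

    ``segments`` maps lncRNA database entry ids to their polypeptide
    sequences; each group's representative is the member segment carrying
    the most of its unique peptides (ties: longest, then lexicographically
    smallest entry id), and peptide occurrence intervals are located on it.
    """
    groups = group_shared_peptides(evidence)
    kept: list[PolypeptideGroup] = []
    for g in groups:
        member_entries = [
            e
            for e in segments
            if e.startswith(LNC_PREFIX + "|")
            and transcript_of_entry(e) in g.member_transcript_ids
        ]
        if not member_entries:
            continue

        def support(entry: str) -> int:
            return sum(1 for p in g.unique_peptides if p in segments[entry])

        rep = sorted(
            member_entries, key=lambda e: (-support(e), -len(segments[e]), e)
        )[0]
        g.representative_entry = rep
        rep_seq = segments[rep]
        occs: list[PeptideOccurrence] = []
        for pep in g.unique_peptides:
            occs.extend(locate_occurrences(pep, rep_seq, g.group_id))
        g.occurrences = occs
        g.nonoverlap_count = count_nonoverlapping_unique(occs)
        if g.nonoverlap_count >= min_nonoverlap:
            kept.append(g)
    matrix = pd.DataFrame(
        {
            s: {g.group_id: median_lfq(g, evidence, s) for g in kept}
            for s in evidence.samples
        }
    )
    matrix = matrix.reindex(sorted(g.group_id for g in kept))
    matrix.index.name = "group_id"
    for g in kept:
        g.abundance = matrix.loc[g.group_id].to_dict()
    return matrix, kept


def write_abundance_tsv(matrix: pd.DataFrame, groups: list[PolypeptideGroup], path) -> None:
    meta = pd.DataFrame(
        {
            "members": {
                g.group_id: ";".join(g.member_transcript_ids) for g in groups
            },
            "n_unique": {g.group_id: len(g.unique_peptides) for g in groups},
            "n_nonoverlap": {g.group_id: g.nonoverlap_count for g in groups},
        }
    )
    out = meta.join(matrix)
    out.index.name = "group_id"
    out.to_csv(path, sep="\t", na_rep="NA")
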