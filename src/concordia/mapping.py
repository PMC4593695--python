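"""Correspondence between microarray probes and RNA-seq feature probes.

Two methods are combined. The *sequence* method asks, for each array probe,
whether its ~70-mer (or its reverse complement) occurs as a contiguous
substring of any feature probe's spanned sequence on the probe's design
chromosome — exact matching, no mismatches, which is the natural semantics
for a hybridization probe. When the sequence method finds nothing, an
*ID fallback* scans the probe's transcript IDs in sorted order and takes the
first one carried by any feature probe. When the sequence method finds
several candidates (typically splice variants of one gene), a candidate
sharing one of the probe's transcript IDs wins; otherwise the candidate with
the lexicographically smallest probe id is taken and flagged ambiguous, a
deterministic stand-in for an arbitrary choice.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .probes import ArrayProbe, ExpressionProbe, reverse_complement

METHOD_SEQUENCE = "sequence"
METHOD_ENSEMBL = "ensembl"


@dataclass
class ProbeMapping:
    """Resolved array-probe -> feature-probe assignments.

    ``entries`` is indexed by array_probe_id with columns ``seq_probe_id``,
    ``method`` (sequence | ensembl) and ``ambiguous`` (bool). ``unmapped``
    lists array probes with no assignment. Several array probes may share one
    feature probe.
    """

    entries: pd.DataFrame
    unmapped: list[str]
    n_array_probes: int
    n_seq_probes: int

    def seq_probe_for(self, array_probe_id: str) -> str | None:
        if array_probe_id in self.entries.index:
            return str(self.entries.loc[array_probe_id, "seq_probe_id"])
        return None

    @property
    def unique_seq_probes(self) -> set[str]:
        return set(self.entries["seq_probe_id"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.entries.copy()
        out["ambiguous"] = out["ambiguous"].astype(int)
        out.rename_axis("array_probe_id").to_csv(path, sep="\t")


def map_by_sequence(
    array_probes: Sequence[ArrayProbe],
    seq_probes: Sequence[ExpressionProbe],
    revcomp: bool = True,
) -> dict[str, list[str]]:
    """Sequence-method candidate sets, keyed by array probe id.

    A feature probe is a candidate iff it lies on the array probe's design
    chromosome and its spanned sequence contains the probe sequence (or, if
    ``revcomp``, its reverse complement) as a contiguous substring.
    Candidates are returned sorted; an empty list is a valid outcome.
    """
    by_chrom: dict[str, list[ExpressionProbe]] = {}
    for r in seq_probes:
        by_chrom.setdefault(r.chromosome, []).append(r)
    out: dict[str, list[str]] = {}
    for m in array_probes:
        pats = [m.sequence] + ([reverse_complement(m.sequence)] if revcomp else [])
        cands = [
            r.probe_id
            for r in by_chrom.get(m.chromosome, [])
            if any(p in r.sequence for p in pats)
        ]
        out[m.probe_id] = sorted(cands)
    return out


def map_by_ensembl(
    array_probe: ArrayProbe, seq_probes_by_id: Mapping[str, str]
) -> str | None:
    """ID-fallback: first transcript ID (in sorted order) carried by a feature probe.

    ``seq_probes_by_id`` maps transcript id -> feature probe id. Probes with
    no transcript IDs cannot be mapped this way and yield ``None``.
    """
    for e in sorted(array_probe.ensembl_ids):
        if e in seq_probes_by_id:
            return seq_probes_by_id[e]
    return None


def resolve_mapping(
    array_probes: Sequence[ArrayProbe],
    seq_probes: Sequence[ExpressionProbe],
    revcomp: bool = True,
) -> ProbeMapping:
    """Run both methods and resolve every array probe deterministically.

    Resolution per probe: a single sequence candidate is taken as-is;
    among multiple candidates one sharing a transcript ID with the probe is
    preferred (smallest feature-probe id if several share), otherwise the
    lexicographically smallest candidate is taken with ``ambiguous=True``;
    with no sequence candidate the ID fallback is attempted; failing that the
    probe is unmapped. The result is independent of input row order.
    """
    ids = [p.probe_id for p in array_probes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array probe ids")
    candidates = map_by_sequence(array_probes, seq_probes, revcomp=revcomp)
    by_id = {r.ensembl_id: r.probe_id for r in sorted(seq_probes, key=lambda r: r.probe_id)}
    seq_probe_ids = {r.probe_id: r for r in seq_probes}

    rows = []
    unmapped: list[str] = []
    for m in sorted(array_probes, key=lambda p: p.probe_id):
        cands = candidates[m.probe_id]
        if len(cands) == 1:
            rows.append((m.probe_id, cands[0], METHOD_SEQUENCE, False))
        elif len(cands) > 1:
            id_consistent = [
                c for c in cands if seq_probe_ids[c].ensembl_id in m.ensembl_ids
            ]
            if id_consistent:
                rows.append((m.probe_id, id_consistent[0], METHOD_SEQUENCE, False))
            else:
                rows.append((m.probe_id, cands[0], METHOD_SEQUENCE, True))
        else:
            fallback = map_by_ensembl(m, by_id)
            if fallback is not None:
                rows.append((m.probe_id, fallback, METHOD_ENSEMBL, False))
            else:
                unmapped.append(m.probe_id)
    entries = pd.DataFrame(
        rows, columns=["array_probe_id", "seq_probe_id", "method", "ambiguous"]
    ).set_index("array_probe_id")
    return ProbeMapping(
        entries=entries,
        unmapped=unmapped,
        n_array_probes=len(array_probes),
        n_seq_probes=len(seq_probes),
    )


@dataclass(frozen=True)
class MappingSummary:
    n_array_probes: int
    n_mapped: int
    percent_mapped: int
    n_unique_seq_probes: int
    n_seq_probes: int
    percent_of_seq_probes: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def summarize_counts(
    n_array_probes: int, n_mapped: int, n_unique_seq_probes: int, n_seq_probes: int
) -> MappingSummary:
    """Mapping summary arithmetic on raw counts.

    ``percent_mapped`` = 100 * mapped/total array probes, reported to the
    nearest integer; ``percent_of_seq_probes`` = 100 * unique matched feature
    probes / total feature probes, reported to one decimal.
    """
    pct_mapped = round(100.0 * n_mapped / n_array_probes) if n_array_probes else 0
    pct_seq = round(100.0 * n_unique_seq_probes / n_seq_probes, 1) if n_seq_probes else 0.0
    return MappingSummary(
        n_array_probes=n_array_probes,
        n_mapped=n_mapped,
        percent_mapped=int(pct_mapped),
        n_unique_seq_probes=n_unique_seq_probes,
        n_seq_probes=n_seq_probes,
        percent_of_seq_probes=pct_seq,
    )


def mapping_summary(mapping: ProbeMapping) -> MappingSummary:
    """Headline counts of a resolved mapping."""
    return summarize_counts(
        n_array_probes=mapping.n_array_probes,
        n_mapped=len(mapping.entries),
        n_unique_seq_probes=len(mapping.unique_seq_probes),
        n_seq_probes=mapping.n_seq_probes,
    )
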