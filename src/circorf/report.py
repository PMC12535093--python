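"""Candidate screening report.

Implements the screen that singles out a coding circle: a candidate passes
iff it is suppressed at both timepoints (sustained down), carries an ORF
that crosses the back-splice junction at least once, and has an RRACH m6A
motif within the upstream window of that ORF's start codon.  Passing
candidates are ranked by strongest mean suppression, then by day-20
p-value, then lexicographically by id so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .de import DifferentialResult
from .orf import CircOrf, MotifHit, peptide_mass

__all__ = ["CandidateRecord", "rank_candidates", "report_table"]


@dataclass
class CandidateRecord:
    """Full screening outcome for one circRNA."""

    circ_id: str
    mean_rpm: float
    log2fc: dict
    p_value: dict
    call: dict
    sustained_down: bool
    best_orf: CircOrf | None
    best_motif: MotifHit | None
    peptide_mass_da: float | None
    screen_pass: bool
    rank: int = 0


def _best_orf(orfs: list) -> CircOrf | None:
    """Longest junction-crossing ORF, ties broken by start position."""
    crossing = [o for o in orfs if o.junction_crossings >= 1]
    if not crossing:
        return None
    return min(crossing, key=lambda o: (-o.aa_length, o.start))


def _best_motif(motifs: list) -> MotifHit | None:
    """In-window motif closest upstream of the start codon."""
    inside = [m for m in motifs if m.within_window]
    if not inside:
        return None
    return min(inside, key=lambda m: (m.upstream_gap, m.start))


def rank_candidates(
    de_results: dict,
    orfs: dict,
    motifs: dict,
    rpms: dict,
    timepoint_for_p: str | None = None,
) -> list:
    """Assemble and rank :class:`CandidateRecord` for every circRNA.

    Parameters
    ----------
    de_results : dict circ_id -> DifferentialResult
    orfs : dict circ_id -> list of CircOrf
        Junction-crossing ORFs found on the circle (may be empty/missing).
    motifs : dict circ_id -> list of MotifHit
        RRACH hits relative to the best ORF start (may be empty/missing).
    rpms : dict circ_id -> float
        Mean per-sample RPM.
    timepoint_for_p : str, optional
        Timepoint whose p-value breaks ranking ties (default: the last
        timepoint in sorted order, i.e. the later one).

    Raises on circ_ids present in orfs/motifs/rpms but absent from
    ``de_results`` (or missing RPMs), listing the orphans.
    """
    ids = set(de_results)
    orphans = sorted(
        (set(orfs) | set(motifs) | set(rpms)) - ids | (ids - set(rpms))
    )
    if orphans:
        raise ValueError(f"circ_ids not keyed consistently across inputs: {orphans}")

    timepoints = sorted({tp for r in de_results.values() for tp in r.call})
    tp_p = timepoint_for_p or (timepoints[-1] if timepoints else None)

    records = []
    for cid in sorted(ids):
        de: DifferentialResult = de_results[cid]
        best_orf = _best_orf(orfs.get(cid, []))
        best_motif = _best_motif(motifs.get(cid, []))
        screen_pass = bool(de.sustained_down and best_orf and best_motif)
        records.append(
            CandidateRecord(
                circ_id=cid,
                mean_rpm=float(rpms[cid]),
                log2fc=dict(de.log2fc),
                p_value=dict(de.p_value),
                call=dict(de.call),
                sustained_down=de.sustained_down,
                best_orf=best_orf,
                best_motif=best_motif,
                peptide_mass_da=peptide_mass(best_orf.peptide) if best_orf and best_orf.peptide else None,
                screen_pass=screen_pass,
            )
        )

    def sort_key(r: CandidateRecord):
        mean_lfc = sum(r.log2fc.values()) / max(len(r.log2fc), 1)
        p_late = r.p_value.get(tp_p, 1.0) if tp_p else 1.0
        return (not r.screen_pass, mean_lfc, p_late, r.circ_id)

    records.sort(key=sort_key)
    for i, r in enumerate(records, start=1):
        r.rank = i
    return records


def report_table(records: list) -> pd.DataFrame:
    """Flatten candidate records to a tidy report table."""
    rows = []
    for r in records:
        row = {
            "rank": r.rank,
            "circ_id": r.circ_id,
            "screen_pass": r.screen_pass,
            "sustained_down": r.sustained_down,
            "mean_rpm": r.mean_rpm,
        }
        for tp in sorted(r.log2fc):
            row[f"log2fc_{tp}"] = r.log2fc[tp]
            row[f"p_{tp}"] = r.p_value[tp]
            row[f"call_{tp}"] = r.call[tp]
        if r.best_orf:
            row.update(
                orf_start=r.best_orf.start,
                orf_aa_length=r.best_orf.aa_length,
                orf_stop_start=r.best_orf.stop_start,
                orf_crossings=r.best_orf.junction_crossings,
                orf_wraps=round(r.best_orf.wraps, 4),
                orf_infinite=r.best_orf.is_infinite,
                peptide_mass_da=round(r.peptide_mass_da, 2) if r.peptide_mass_da else None,
            )
        if r.best_motif:
            row.update(
                motif_start=r.best_motif.start,
                motif_end=r.best_motif.end,
                motif_seq=r.best_motif.motif_seq,
                motif_upstream_gap=r.best_motif.upstream_gap,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(records: list, tsv_path, json_path=None) -> None:
    table = report_table(records)
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        payload = json.loads(table.to_json(orient="records"))
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
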