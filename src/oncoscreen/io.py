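"""Readers and writers for the screen's plain-text interchange formats.

All tables are tab-delimited UTF-8 with ``#``-prefixed comment header
lines recording provenance (config and seed).  Coordinates are 0-based
half-open internally and in BED output; GTF input would be converted
from 1-based inclusive on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .survival import SurvivalCohort
from .alterations import AlterationMatrix, MirnaTargetMap
from .splicing import SplicingEvent

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_survival_tsv", "read_survival_tsv",
    "write_alterations_tsv", "read_alterations_tsv",
    "write_events_tsv", "read_events_tsv",
    "write_fasta", "read_fasta",
    "write_events_bed",
    "write_ground_truth_json",
    "read_mirna_targets_tsv", "write_mirna_targets_tsv",
    "read_gene_list",
]


def _comment_block(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_counts_tsv(path, matrix: CountMatrix, meta: dict | None = None) -> None:
    """Genes x samples count TSV with a group-label comment line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_comment_block(meta))
        fh.write("# groups: " + ",".join(matrix.group_labels) + "\n")
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene_id")


def read_counts_tsv(path, groups: list[str] | None = None) -> CountMatrix:
    """Read a counts TSV; group labels come from the ``# groups:`` header
    comment unless given explicitly (or via a sidecar list)."""
    path = Path(path)
    header_groups = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# groups:"):
                header_groups = line.split(":", 1)[1].strip().split(",")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    labels = groups if groups is not None else header_groups
    if labels is None:
        raise ValueError(f"{path}: no group labels in header and none supplied")
    return CountMatrix(list(df.index), list(df.columns), df.to_numpy(), list(labels))


def write_survival_tsv(path, cohort: SurvivalCohort, meta: dict | None = None) -> None:
    """sample / time / event columns followed by one column per gene."""
    df = pd.DataFrame({
        "sample": cohort.sample_ids,
        "time": cohort.time,
        "event": cohort.event,
    }).set_index("sample")
    df = df.join(cohort.expression)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_comment_block(meta))
        if cohort.reference_samples:
            fh.write("# reference_samples: " + ",".join(cohort.reference_samples) + "\n")
        df.to_csv(fh, sep="\t")


def read_survival_tsv(path) -> SurvivalCohort:
    path = Path(path)
    reference = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# reference_samples:"):
                reference = line.split(":", 1)[1].strip().split(",")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    expr = df.drop(columns=["time", "event"])
    return SurvivalCohort(
        list(df.index), df["time"].to_numpy(), df["event"].to_numpy(),
        expr, reference_samples=reference,
    )


def write_alterations_tsv(path, matrix: AlterationMatrix,
                          meta: dict | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_comment_block(meta))
        matrix.to_frame().to_csv(fh, sep="\t", index_label="sample")


def read_alterations_tsv(path) -> AlterationMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return AlterationMatrix(list(df.index), list(df.columns), df.to_numpy())


def write_events_tsv(path, events: list[SplicingEvent],
                     meta: dict | None = None) -> None:
    """One row per event with per-replicate counts as comma-joined lists."""
    rows = []
    for ev in events:
        conds = sorted(ev.inclusion_counts)
        row = {
            "event_id": ev.event_id, "event_type": ev.event_type,
            "gene_id": ev.gene_id, "chrom": ev.chrom, "strand": ev.strand,
            "start": ev.start, "end": ev.end,
            "eff_len_inclusion": ev.effective_length_inclusion,
            "eff_len_skipping": ev.effective_length_skipping,
        }
        for cond in conds:
            row[f"inclusion_{cond}"] = ",".join(map(str, ev.inclusion_counts[cond]))
            row[f"skipping_{cond}"] = ",".join(map(str, ev.skipping_counts[cond]))
        rows.append(row)
    df = pd.DataFrame(rows)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_comment_block(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_events_tsv(path) -> list[SplicingEvent]:
    df = pd.read_csv(path, sep="\t", comment="#")
    inc_cols = [c for c in df.columns if c.startswith("inclusion_")]
    events = []
    for _, row in df.iterrows():
        inc, skp = {}, {}
        for col in inc_cols:
            cond = col[len("inclusion_"):]
            inc[cond] = np.array([int(x) for x in str(row[col]).split(",")])
            skp[cond] = np.array([int(x) for x in str(row[f"skipping_{cond}"]).split(",")])
        events.append(SplicingEvent(
            event_id=row["event_id"], event_type=row["event_type"],
            gene_id=row.get("gene_id", ""), chrom=row["chrom"],
            strand=row["strand"], start=int(row["start"]), end=int(row["end"]),
            inclusion_counts=inc, skipping_counts=skp,
            effective_length_inclusion=float(row["eff_len_inclusion"]),
            effective_length_skipping=float(row["eff_len_skipping"]),
        ))
    return events


def write_fasta(path, genome: dict, width: int = 70) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    """Plain FASTA into a dict of sequences (small genomes only; use
    pyfaidx.Fasta for indexed access to larger files)."""
    genome: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        genome[name] = "".join(parts)
    return genome


def write_events_bed(path, events: list[SplicingEvent]) -> None:
    """0-based half-open BED6 of the alternative segments."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.event_id}\t0\t{ev.strand}\n")


def write_ground_truth_json(path, truth, config=None) -> None:
    payload = {"ground_truth": truth.to_dict()}
    if config is not None:
        payload["config"] = config.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def write_mirna_targets_tsv(path, target_map: MirnaTargetMap) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# universe_size: {target_map.universe_size}\n")
        for mirna, genes in target_map.targets.items():
            for g in sorted(genes):
                fh.write(f"{mirna}\t{g}\n")


def read_mirna_targets_tsv(path, universe_size: int | None = None) -> MirnaTargetMap:
    """Two-column miRNA / target TSV; universe size from the header
    comment unless overridden."""
    path = Path(path)
    targets: dict[str, set] = {}
    header_universe = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "universe_size:" in line:
                    header_universe = int(line.split(":", 1)[1])
                continue
            mirna, gene = line.split("\t")[:2]
            targets.setdefault(mirna, set()).add(gene)
    size = universe_size if universe_size is not None else header_universe
    if size is None:
        size = len({g for s in targets.values() for g in s})
    return MirnaTargetMap(targets, size)


def read_gene_list(path) -> list[str]:
    """One gene id per line, '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out
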