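"""Readers and writers for the package's standard file formats.

Spacer tables are TSV/CSV with CRISPick-style annotation columns;
libraries are emitted as FASTA (one record per construct) plus a TSV
manifest; reads as paired FASTQ; intervals as BED (0-based half-open).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import GenomicInterval, assign_direct_repeats
from .records import ArrayConstruct, ConstructLibrary, Spacer
from .simulate import SimulatedFragment

__all__ = [
    "read_spacer_table",
    "write_spacer_table",
    "write_library",
    "read_library",
    "write_paired_fastq",
    "read_paired_fastq",
    "read_bed",
    "write_bed",
    "write_counts",
    "read_counts",
]

SPACER_COLUMNS = [
    "id",
    "sequence",
    "category",
    "target_id",
    "pam",
    "pam_class",
    "tss_offset",
    "on_target_efficacy",
    "offtarget_match",
    "tier1_bin1_matches",
]


def read_spacer_table(path: str | Path) -> list[Spacer]:
    """Load spacers from a TSV/CSV table (delimiter inferred from suffix)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
    missing = {"id", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"spacer table lacks required columns {sorted(missing)}")
    spacers = []
    for _, row in df.iterrows():
        def _get(col, default=None):
            v = row.get(col)
            return default if v is None or pd.isna(v) else v

        sp = Spacer(
            id=str(row["id"]),
            sequence=str(row["sequence"]).upper(),
            category=str(_get("category", "tss_targeting")),
            target_id=str(_get("target_id", "")),
            pam=str(_get("pam", "")),
            pam_class=str(_get("pam_class", "canonical_TTTV")),
            tss_offset=(
                int(_get("tss_offset")) if _get("tss_offset") is not None else None
            ),
            on_target_efficacy=(
                float(_get("on_target_efficacy"))
                if _get("on_target_efficacy") is not None
                else None
            ),
            offtarget_match_flag=str(_get("offtarget_match", "")),
            tier1_bin1_matches=(
                int(_get("tier1_bin1_matches"))
                if _get("tier1_bin1_matches") is not None
                else None
            ),
        )
        sp.validate()
        spacers.append(sp)
    return spacers


def write_spacer_table(spacers: Sequence[Spacer], path: str | Path) -> None:
    rows = [
        {
            "id": s.id,
            "sequence": s.sequence,
            "category": s.category,
            "target_id": s.target_id,
            "pam": s.pam,
            "pam_class": s.pam_class,
            "tss_offset": s.tss_offset,
            "on_target_efficacy": s.on_target_efficacy,
            "offtarget_match": s.offtarget_match_flag,
            "tier1_bin1_matches": s.tier1_bin1_matches,
        }
        for s in spacers
    ]
    pd.DataFrame(rows, columns=SPACER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_library(
    library: ConstructLibrary,
    fasta_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Emit a library as FASTA plus a TSV manifest."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in library
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "construct_id": c.id,
            "plex": c.plex,
            "dr_names": ",".join(c.dr_assignment.names),
            "spacer_ids": ",".join(c.spacer_ids),
            "spacer_seqs": ",".join(c.spacer_tuple),
            "test_position": c.test_position,
            "context_set_id": c.context_set_id,
        }
        for c in library
    ]
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_library(
    fasta_path: str | Path, manifest_path: str | Path
) -> ConstructLibrary:
    """Reconstruct a library from FASTA + manifest."""
    seqs = {
        r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")
    }
    manifest = pd.read_csv(manifest_path, sep="\t")
    lib = ConstructLibrary()
    for _, row in manifest.iterrows():
        plex = int(row["plex"])
        dr_names = str(row["dr_names"]).split(",")
        dra = assign_direct_repeats(plex, custom=dr_names)
        spacer_ids = str(row["spacer_ids"]).split(",")
        spacer_seqs = str(row["spacer_seqs"]).split(",")
        spacers = tuple(
            Spacer(id=i, sequence=s, category="intergenic_negative")
            for i, s in zip(spacer_ids, spacer_seqs)
        )
        cid = str(row["construct_id"])
        tp = row.get("test_position")
        ctx = row.get("context_set_id")
        lib.add(
            ArrayConstruct(
                id=cid,
                spacers=spacers,
                dr_assignment=dra,
                sequence=seqs[cid],
                test_position=None if pd.isna(tp) else int(tp),
                context_set_id=None if pd.isna(ctx) else str(ctx),
            )
        )
    return lib


def write_paired_fastq(
    fragments: Iterable[SimulatedFragment],
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: Optional[str | Path] = None,
    quality: int = 37,
) -> None:
    """Write simulated fragments as paired FASTQ plus a truth-label TSV."""
    qchar = chr(quality + 33)
    truth_rows = []
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for frag in fragments:
            for fh, seq in ((f1, frag.r1), (f2, frag.r2)):
                fh.write(
                    f"@{frag.read_id}\n{seq}\n+\n{qchar * len(seq)}\n"
                )
            truth_rows.append(
                {
                    "read_id": frag.read_id,
                    "truth": frag.truth,
                    "construct_id": frag.construct_id or "",
                    "parents": ",".join(frag.parents) if frag.parents else "",
                    "junction": frag.junction,
                }
            )
    if truth_path is not None:
        pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)


def read_paired_fastq(
    r1_path: str | Path, r2_path: str | Path
) -> list[tuple[str, str, str]]:
    """Load read pairs as (read id, R1, R2); ids must correspond in order."""
    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"),
        SeqIO.parse(str(r2_path), "fastq"),
        strict=True,
    ):
        if rec1.id != rec2.id:
            raise ValueError(
                f"mate id mismatch: {rec1.id!r} vs {rec2.id!r}"
            )
        out.append((rec1.id, str(rec1.seq), str(rec2.seq)))
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="construct")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="construct")
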