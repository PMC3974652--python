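"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; tabular data as TSV via pandas; BED written
0-based half-open (internal coordinates stay 1-based inclusive).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import Interval
from .synthetic_data import SyntheticRead, TilingExperiment, TruthAlignment


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(path: str | Path, rows: list[tuple[str, Interval, str]]) -> None:
    """Rows are (chrom, interval, name); converted to 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, iv, name in rows:
            fh.write(
                f"{chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def write_tiling_tsv(path: str | Path, experiment: TilingExperiment) -> None:
    experiment.data.to_csv(path, sep="\t", index=False)


def read_tiling_tsv(
    path: str | Path,
    assay: str,
    anchors: dict[tuple[str, str], int] | None = None,
) -> TilingExperiment:
    """Rebuild a tiling experiment from the tidy TSV schema.

    Truth is unknown for external data (empty mapping is used only to
    enumerate groups, so it is reconstructed from the table).  Anchors
    default to 1 (probe offsets then double as positions).
    """
    from .synthetic_data import ASSAY_SIZES

    data = pd.read_csv(path, sep="\t")
    groups = sorted(set(zip(data.hairpin_id, data.arm)))
    return TilingExperiment(
        assay=assay,
        end_type="3prime" if assay == "3p-assay" else "5prime",
        n_probes=ASSAY_SIZES[assay],
        replicates=int(data.replicate.max()) + 1,
        data=data,
        truth={g: -1 for g in groups},
        anchors=anchors or {g: 1 for g in groups},
    )


def write_expression_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edges_tsv(path: str | Path, edges: list[tuple[str, str]]) -> None:
    pd.DataFrame(edges, columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))


def write_sam(
    path: str | Path,
    reads: list[SyntheticRead],
    alignments: list[TruthAlignment],
    references: dict[str, int],
) -> None:
    """Minimal text SAM with NM tags (enough for the built-in parser)."""
    seq_by_read = {r.read_id: r.sequence for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref, length in references.items():
            fh.write(f"@SQ\tSN:{ref}\tLN:{length}\n")
        for a in alignments:
            seq = seq_by_read.get(a.read_id, "*")
            cigar = f"{a.length}M"
            fh.write(
                f"{a.read_id}\t0\t{a.ref_id}\t{a.pos}\t255\t{cigar}\t*\t0\t0"
                f"\t{seq}\t*\tNM:i:{a.n_mismatches}\n"
            )


def read_config(path: str | Path) -> dict[str, str]:
    """key=value config file (blank lines and # comments skipped)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
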