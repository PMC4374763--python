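"""Readers and writers for region tables, phage protein databases and tracks.

Region tables come in two flavours:

* native TSV — 1-based inclusive, columns ``label  start  end  [strand]``,
  optionally with a header line starting with ``#`` or ``label``;
* BED — 0-based half-open ``chrom  start  end  name``; converted to the
  native convention on read.

The phage protein database is a FASTA whose headers carry
``id|phage_name|family``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

from Bio import SeqIO

from .genome import GenomeError, GenomicRegion


@dataclass(frozen=True)
class DbProtein:
    """One phage protein database record with its taxonomy metadata."""

    id: str
    phage: str
    family: str
    sequence: str


def read_region_table(path: str | os.PathLike, genome_id: str = "") -> list[GenomicRegion]:
    """Read regions from native TSV (1-based inclusive) or BED (by extension)."""
    path = os.fspath(path)
    if path.lower().endswith(".bed"):
        return read_bed(path)
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in {"label", "name", "region"}:
                continue
            if len(parts) < 3:
                raise GenomeError(f"{path}: expected >=3 tab-separated columns: {line!r}")
            label, start, end = parts[0], int(parts[1]), int(parts[2])
            regions.append(GenomicRegion(label=label, start=start, end=end,
                                         genome_id=genome_id))
    return regions


def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"{path}: malformed BED line: {line!r}")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            # BED is 0-based half-open; native is 1-based inclusive
            regions.append(GenomicRegion(label=label, start=start0 + 1, end=end0,
                                         genome_id=chrom))
    return regions


def write_region_table(regions: list[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "start", "end"])
        for r in regions:
            w.writerow([r.label, r.start, r.end])


def write_bed(regions: list[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.genome_id or 'genome'}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_phage_db(path: str | os.PathLike) -> list[DbProtein]:
    """Read a phage protein FASTA with ``id|phage_name|family`` headers.

    Records with fewer than three ``|``-separated fields keep empty phage or
    family strings rather than failing, so plain FASTA databases still load.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        parts = rec.id.split("|")
        pid = parts[0]
        phage = parts[1] if len(parts) > 1 else ""
        family = parts[2] if len(parts) > 2 else ""
        records.append(DbProtein(id=pid, phage=phage, family=family,
                                 sequence=str(rec.seq).upper()))
    if not records:
        raise GenomeError(f"{os.fspath(path)}: empty protein database")
    return records


def write_phage_db(records: list[DbProtein], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}|{r.phage}|{r.family}\n{r.sequence}\n")


def write_bedgraph(track, genome_id: str, path: str | os.PathLike) -> None:
    """Write an NPKM (or any windowed) track as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="NPKM w={track.window_size}"\n')
        for region, value in track.values:
            fh.write(f"{genome_id}\t{region.start - 1}\t{region.end}\t{value:.6g}\n")
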