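"""Reading and writing the package's on-disk formats.

References and reads travel as plain FASTA/FASTQ (via Biopython); truth
tables and per-read results as TSV; donor metadata, site plans and reports
as JSON.  A reference-set directory contains::

    references.fasta   wt_locus + integrated_locus
    features.fasta     the six annotation features
    donor.json         donor sequences, ddPCR oligos, nick_site
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refsim import (DonorSpec, OutcomeSpec, ReferenceSet, SimulatedRead,
                     SiteEntry, SitePlan)


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Sequence[SimulatedRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path) -> list[SimulatedRead]:
    reads = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(SimulatedRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def save_reference_set(refset: ReferenceSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "references.fasta", [
        ("wt_locus", refset.wt_locus),
        ("integrated_locus", refset.integrated_locus),
    ])
    write_fasta(outdir / "features.fasta", sorted(refset.feature_library.items()))
    donor = dataclasses.asdict(refset.donor)
    donor["nick_site"] = refset.nick_site
    (outdir / "donor.json").write_text(json.dumps(donor, indent=1))


def load_reference_set(refdir) -> ReferenceSet:
    refdir = Path(refdir)
    refs = read_fasta(refdir / "references.fasta")
    features = read_fasta(refdir / "features.fasta")
    meta = json.loads((refdir / "donor.json").read_text())
    nick = meta.pop("nick_site")
    donor = DonorSpec(**meta)
    refset = ReferenceSet(refs["wt_locus"], nick, donor,
                          refs["integrated_locus"], features)
    refset.validate()
    return refset


def write_truth_table(path, reads: Sequence[SimulatedRead]) -> None:
    rows = []
    for r in reads:
        rows.append({
            "read_id": r.read_id,
            "category": r.truth.category if r.truth else None,
            "truncation_point": r.truth.truncation_point if r.truth else None,
            "truth_site": r.truth_site,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_site_plan(path, plan: SitePlan) -> None:
    data = [dataclasses.asdict(e) for e in plan.entries]
    Path(path).write_text(json.dumps(data, indent=1))


def load_site_plan(path) -> SitePlan:
    data = json.loads(Path(path).read_text())
    return SitePlan(tuple(SiteEntry(**e) for e in data))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
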