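"""Readers and writers for the dataset interchange formats.

On disk the dataset is plain text: FASTA contigs and CDS pairs, a VCF v4.2
with per-sample GT, per-individual BED depth files, a BED4 repeat track, a
GFF3 gene annotation, TSV maps (sex, markers, X-Y alignment) and a JSON
truth file.  Coordinates are 0-based half-open internally and only become
1-based in VCF/GFF3 serialization.  ``write_dataset`` / ``read_dataset``
round-trip the in-memory objects field for field.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import InputError
from .simulate import (
    Contig, Gene, GenePair, GenomeModel, RepeatInterval, SampleSet,
)

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
# cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
_GT_CODE = {0: 0, 1: 1, 2: -1, 3: 2}


# --- FASTA -----------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# --- VCF -------------------------------------------------------------------

def write_vcf(samples: SampleSet, contig_lengths: dict[str, int],
              path) -> None:
    ids = samples.ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrscan-simulate\n")
        for cid, length in contig_lengths.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write('##INFO=<ID=CAT,Number=1,Type=String,'
                 'Description="Simulated site category">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        v = samples.variants
        for i in range(len(v)):
            row = v.iloc[i]
            gts = "\t".join(_GT_STR[int(g)] for g in samples.gt[i])
            fh.write(f"{row['contig']}\t{int(row['pos']) + 1}\t.\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t"
                     f"CAT={row['category']}\tGT\t{gts}\n")


def read_vcf(path, individuals: list[tuple[str, str]]
             ) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a VCF into (variants frame, genotype dosage matrix).

    Genotypes are recoded as ALT dosage with -1 for missing; sample order
    follows ``individuals`` (which must match the VCF sample set).
    """
    vcf = VCF(str(path), gts012=False)
    ids = [i for i, _ in individuals]
    if list(vcf.samples) != ids:
        order = [vcf.samples.index(i) for i in ids]
    else:
        order = list(range(len(ids)))
    rows, gts = [], []
    for v in vcf:
        cat = v.INFO.get("CAT") or "unknown"
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0], cat))
        codes = np.array([_GT_CODE[t] for t in v.gt_types], dtype=np.int8)
        gts.append(codes[order])
    variants = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "category"])
    gt = (np.vstack(gts) if gts
          else np.empty((0, len(ids)), dtype=np.int8))
    return variants, gt


# --- BED depth / repeats ---------------------------------------------------

def write_depth_beds(samples: SampleSet, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    bins = samples.depth_bins
    for j, ind in enumerate(samples.ids):
        p = outdir / f"{ind}.bed"
        df = bins.copy()
        df["depth"] = samples.depth[:, j]
        df.to_csv(p, sep="\t", header=False, index=False)
        paths.append(p)
    return paths


def read_depth_beds(depth_dir, individuals: list[tuple[str, str]]
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    depth_dir = Path(depth_dir)
    bins = None
    cols = []
    for ind, _ in individuals:
        df = pd.read_csv(depth_dir / f"{ind}.bed", sep="\t", header=None,
                         names=["contig", "start", "end", "depth"])
        this_bins = df[["contig", "start", "end"]]
        if bins is None:
            bins = this_bins
        elif not bins.equals(this_bins):
            raise InputError(f"depth bins of {ind!r} do not match")
        cols.append(df["depth"].to_numpy(float))
    return bins, np.column_stack(cols)


def write_repeats_bed(repeats: list[RepeatInterval], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats,
                        key=lambda r: (r.contig, r.start, r.end, r.cls)):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.cls}\n")


def read_repeats_bed(path) -> list[RepeatInterval]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "cls"])
    return [RepeatInterval(r.contig, int(r.start), int(r.end), r.cls)
            for r in df.itertuples()]


# --- GFF3 ------------------------------------------------------------------

def write_gff3(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.id)):
            fh.write(f"{g.contig}\tsdrscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}\n")
            fh.write(f"{g.contig}\tsdrscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.id}.t1;Parent={g.id}\n")
            for k, (s, e) in enumerate(g.exons):
                fh.write(f"{g.contig}\tsdrscan\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.id}.exon{k + 1};"
                         f"Parent={g.id}.t1\n")


def read_gff3(path) -> list[Gene]:
    db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                            merge_strategy="error")
    genes = []
    for f in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(f, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon",
                                  order_by="start"):
                exons.append((ex.start - 1, ex.end))
        genes.append(Gene(f.id, f.seqid, f.start - 1, f.end, f.strand,
                          tuple(sorted(exons))))
    genes.sort(key=lambda g: (g.contig, g.start, g.id))
    return genes


# --- TSV maps --------------------------------------------------------------

def write_sex_map(individuals: list[tuple[str, str]], path) -> None:
    pd.DataFrame(individuals, columns=["individual", "sex"]).to_csv(
        path, sep="\t", index=False)


def read_sex_map(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.individual), str(r.sex)) for r in df.itertuples()]


def write_alignment_map(aln, path) -> None:
    pd.DataFrame(aln, columns=["x_contig", "x_start", "x_end", "y_contig",
                               "y_start", "y_end", "strand"]
                 ).to_csv(path, sep="\t", index=False)


def read_alignment_map(path):
    df = pd.read_csv(path, sep="\t")
    return [(r.x_contig, int(r.x_start), int(r.x_end), r.y_contig,
             int(r.y_start), int(r.y_end), r.strand)
            for r in df.itertuples()]


# --- dataset bundle --------------------------------------------------------

def write_dataset(genome: GenomeModel, samples: SampleSet,
                  pairs: list[GenePair], outdir) -> dict[str, str]:
    """Serialize the full simulated dataset; returns a file manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    write_fasta(genome.sequences, out / "contigs.fasta")
    manifest["contigs"] = "contigs.fasta"

    lengths = {c.id: c.length for c in genome.contigs}
    write_vcf(samples, lengths, out / "variants.vcf")
    manifest["vcf"] = "variants.vcf"

    write_depth_beds(samples, out / "depth")
    manifest["depth_dir"] = "depth"

    write_repeats_bed(genome.repeats, out / "repeats.bed")
    manifest["repeats"] = "repeats.bed"

    write_gff3(genome.genes, out / "genes.gff3")
    manifest["genes"] = "genes.gff3"

    write_sex_map(samples.individuals, out / "sex_map.tsv")
    manifest["sex_map"] = "sex_map.tsv"

    write_alignment_map(genome.alignment_map, out / "alignment_map.tsv")
    manifest["alignment_map"] = "alignment_map.tsv"

    pd.DataFrame(genome.markers, columns=["marker", "contig", "pos"]
                 ).to_csv(out / "markers.tsv", sep="\t", index=False)
    manifest["markers"] = "markers.tsv"
    samples.marker_presence.astype(int).to_csv(
        out / "marker_presence.tsv", sep="\t")
    manifest["marker_presence"] = "marker_presence.tsv"

    if pairs:
        cds = {}
        for k, pair in enumerate(pairs):
            cds[f"pair{k + 1}_parent"] = pair.parent_cds
            cds[f"pair{k + 1}_duplicate"] = pair.duplicate_cds
        write_fasta(cds, out / "cds_pairs.fasta")
        manifest["cds_pairs"] = "cds_pairs.fasta"

    truth = {
        "contigs": [[c.id, c.length, c.true_class] for c in genome.contigs],
        "sdr_truth": list(genome.sdr_truth) if genome.sdr_truth else None,
        "sdg": genome.sdg,
        "sdg_parent": genome.sdg_parent,
        "bin_size": genome.bin_size,
        "y_bin_class": [int(x) for x in genome.y_bin_class],
        "marker_hits": genome.marker_hits,
        "gene_pairs": [
            {k: v for k, v in dataclasses.asdict(p).items()
             if k not in ("parent_cds", "duplicate_cds")}
            for p in pairs
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    manifest["truth"] = "truth.json"
    return manifest


def read_dataset(outdir) -> tuple[GenomeModel, SampleSet, list[GenePair]]:
    """Load a dataset written by :func:`write_dataset`."""
    out = Path(outdir)
    truth = json.loads((out / "truth.json").read_text())

    contigs = [Contig(cid, int(length), cls)
               for cid, length, cls in truth["contigs"]]
    sequences = read_fasta(out / "contigs.fasta")
    genes = read_gff3(out / "genes.gff3")
    repeats = read_repeats_bed(out / "repeats.bed")
    aln = read_alignment_map(out / "alignment_map.tsv")
    mk = pd.read_csv(out / "markers.tsv", sep="\t")
    markers = [(str(r.marker), str(r.contig), int(r.pos))
               for r in mk.itertuples()]
    genome = GenomeModel(
        contigs=contigs,
        sequences=sequences,
        genes=genes,
        repeats=repeats,
        sdr_truth=(tuple(truth["sdr_truth"]) if truth["sdr_truth"]
                   else None),
        sdg=truth["sdg"],
        sdg_parent=truth["sdg_parent"],
        bin_size=int(truth["bin_size"]),
        y_bin_class=np.array(truth["y_bin_class"], dtype=np.int8),
        marker_hits={k: int(v) for k, v in truth["marker_hits"].items()},
        markers=markers,
        alignment_map=aln,
    )

    individuals = read_sex_map(out / "sex_map.tsv")
    variants, gt = read_vcf(out / "variants.vcf", individuals)
    bins, depth = read_depth_beds(out / "depth", individuals)
    mp = pd.read_csv(out / "marker_presence.tsv", sep="\t", index_col=0)
    mp = mp.astype(bool)
    mp.index = mp.index.astype(str)
    samples = SampleSet(individuals, variants, gt, bins, depth, mp)

    pairs = []
    if truth["gene_pairs"]:
        cds = read_fasta(out / "cds_pairs.fasta")
        for k, meta in enumerate(truth["gene_pairs"]):
            pairs.append(GenePair(
                parent_cds=cds[f"pair{k + 1}_parent"],
                duplicate_cds=cds[f"pair{k + 1}_duplicate"],
                parent_exons=tuple(tuple(x) for x in meta["parent_exons"]),
                kept_exons=tuple(meta["kept_exons"]),
                duplicate_exons=tuple(tuple(x)
                                      for x in meta["duplicate_exons"]),
                true_ks=float(meta["true_ks"]),
                true_ka=float(meta["true_ka"]),
                truncation=tuple(meta["truncation"]),
                saturated_warning=bool(meta["saturated_warning"]),
                seed=int(meta["seed"]),
            ))
    return genome, samples, pairs
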