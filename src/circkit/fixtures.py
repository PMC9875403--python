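"""Deterministic synthetic-data generator.

Emulates everything downstream of read alignment and circRNA quantification:
a toy genome, an ENSEMBL-style gene annotation, a truth set of circRNAs
covering all four annotation classes, per-caller native output files with a
controlled true/false-positive composition, and miRanda/TargetScan result
files with seed sites planted at known positions.

Everything is a pure function of the :class:`FixtureSpec` — the same spec
yields byte-identical files — so tests and benchmarks are reproducible
without any external caller binaries or sequencing reads.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .io import (
    SUPPORTED_TOOLS,
    GeneModel,
    read_gtf,
    write_fasta,
    write_tool_output,
)
from .mirna import MirandaHit, TargetScanHit, write_miranda, write_targetscan
from .records import SITE_TYPES, CircKey, CircRNACall, circ_id


class SpecError(ValueError):
    """The requested geometry or composition cannot be generated."""


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generator; generation is a pure function of this."""

    seed: int = 0
    # reference geometry
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_genes: int = 12
    exons_per_gene: Tuple[int, int] = (3, 6)
    exon_length: Tuple[int, int] = (80, 300)
    intron_length: Tuple[int, int] = (300, 800)
    intergenic_gap: Tuple[int, int] = (1_500, 3_000)
    # truth composition (counts per intended class)
    n_exact_exonic: int = 10
    n_near_exonic: int = 10
    near_offset: Tuple[int, int] = (1, 50)
    ei_offset: Tuple[int, int] = (250, 290)
    n_ei: int = 10
    n_cirna: int = 10
    n_intergenic: int = 10
    # per-tool call composition
    tools: Tuple[str, ...] = SUPPORTED_TOOLS
    samples: Tuple[str, ...] = ("sample_01",)
    tp_count: int = 40
    fp_count: int = 10
    bsj_read_range: Tuple[int, int] = (2, 50)
    # planted miRNA response elements
    n_mirnas: int = 6
    mirna_length: int = 21
    n_planted_pairs: int = 5
    n_miranda_only: int = 3
    n_targetscan_only: int = 2

    @property
    def n_truth(self) -> int:
        return (
            self.n_exact_exonic + self.n_near_exonic + self.n_ei
            + self.n_cirna + self.n_intergenic
        )


@dataclass
class TruthRecord:
    chrom: str
    start: int
    end: int
    strand: str
    label: str  # intended annotation class

    @property
    def key(self) -> CircKey:
        return (self.chrom, self.start, self.end)


@dataclass
class Reference:
    genome: Dict[str, str]
    gtf_text: str
    model: GeneModel


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, alphabet=_BASES) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), size=length)])


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def make_reference(spec: FixtureSpec) -> Reference:
    """Random genome plus a non-overlapping multi-exon gene annotation.

    Genes are laid out left to right with intergenic gaps, alternating
    between chromosomes and strands; every second gene with enough exons gets
    a second transcript that skips one internal exon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genome = {
        f"chr{i + 1}": _random_seq(rng, spec.chrom_length)
        for i in range(spec.n_chroms)
    }
    chroms = list(genome)

    gtf_lines: List[str] = ["#!genome-build circkit-fixture"]
    cursors = {c: 0 for c in chroms}
    for g in range(spec.n_genes):
        chrom = chroms[g % len(chroms)]
        strand = "+" if g % 2 == 0 else "-"
        gap = int(rng.integers(*spec.intergenic_gap, endpoint=True))
        n_exons = int(rng.integers(*spec.exons_per_gene, endpoint=True))
        exon_lens = rng.integers(*spec.exon_length, size=n_exons, endpoint=True)
        intron_lens = rng.integers(
            *spec.intron_length, size=max(n_exons - 1, 0), endpoint=True
        )
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom] + gap
        if start + gene_len > spec.chrom_length - 200:
            raise SpecError(
                f"gene {g + 1} does not fit on {chrom}: increase chrom_length "
                f"or reduce n_genes"
            )
        exons: List[Tuple[int, int]] = []
        pos = start
        for i, exon_len in enumerate(exon_lens):
            exons.append((pos, pos + int(exon_len)))
            pos += int(exon_len)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        cursors[chrom] = exons[-1][1]

        gene_id = f"GENE{g + 1:04d}"
        gene_name = f"SYM{g + 1}"
        attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
        gtf_lines.append(_gtf_line(chrom, "gene", start, exons[-1][1], strand, attrs))

        transcripts = [(f"{gene_id}.t1", exons)]
        if n_exons >= 3 and g % 2 == 0:
            skip = 1 + int(rng.integers(0, n_exons - 2))
            transcripts.append(
                (f"{gene_id}.t2", exons[:skip] + exons[skip + 1:])
            )
        for tx_id, tx_exons in transcripts:
            tx_attrs = attrs + f' transcript_id "{tx_id}";'
            gtf_lines.append(
                _gtf_line(chrom, "transcript", tx_exons[0][0], tx_exons[-1][1],
                          strand, tx_attrs)
            )
            for n, (es, ee) in enumerate(tx_exons, start=1):
                gtf_lines.append(
                    _gtf_line(chrom, "exon", es, ee, strand,
                              tx_attrs + f' exon_number "{n}";')
                )
    gtf_text = "\n".join(gtf_lines) + "\n"

    model = _model_from_text(gtf_text)
    return Reference(genome=genome, gtf_text=gtf_text, model=model)


def _gtf_line(chrom: str, feature: str, start0: int, end0: int, strand: str,
              attrs: str) -> str:
    # GTF is 1-based inclusive
    return "\t".join(
        (chrom, "circkit_fixture", feature, str(start0 + 1), str(end0),
         ".", strand, ".", attrs)
    )


def _model_from_text(gtf_text: str) -> GeneModel:
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as tmp:
        tmp.write(gtf_text)
        path = tmp.name
    try:
        return read_gtf(path)
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# Truth set
# ---------------------------------------------------------------------------

def make_truth(spec: FixtureSpec, reference: Reference) -> List[TruthRecord]:
    """Truth circRNAs with guaranteed-attainable intended classes.

    * exact exonic — ends on exon boundaries of a transcript;
    * near exonic — exact ends shifted outward by 1..near_offset bp
      (still within the default 200 bp boundary tolerance);
    * EI — exact start, end pushed 250..290 bp past the last exon end;
    * ciRNA — strictly inside an intron;
    * intergenic — inside an intergenic gap, clear of every gene span.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    model: GeneModel = reference.model

    # primary transcripts only (deterministic order), with their gene strand
    primaries = sorted(
        (tx for tx in model.transcripts.values() if tx.transcript_id.endswith(".t1")),
        key=lambda tx: tx.transcript_id,
    )
    multi = [tx for tx in primaries if len(tx.exons) >= 2]
    if spec.n_cirna and not multi:
        raise SpecError("ciRNA plants need transcripts with introns")
    if (spec.n_exact_exonic or spec.n_near_exonic or spec.n_ei) and not primaries:
        raise SpecError("exonic plants need at least one gene")

    used: set = set()
    records: List[TruthRecord] = []

    def add(chrom: str, start: int, end: int, strand: str, label: str) -> bool:
        key = (chrom, start, end)
        if key in used or start >= end:
            return False
        used.add(key)
        records.append(TruthRecord(chrom, start, end, strand, label))
        return True

    def pick_tx(pool):
        return pool[int(rng.integers(0, len(pool)))]

    guard = 0
    n_done = 0
    while n_done < spec.n_exact_exonic:
        tx = pick_tx(primaries)
        i = int(rng.integers(0, len(tx.exons)))
        j = int(rng.integers(i, len(tx.exons)))
        if add(tx.chrom, tx.exons[i][0], tx.exons[j][1], tx.strand, "circRNA"):
            n_done += 1
        guard = _bump(guard)

    n_done = 0
    while n_done < spec.n_near_exonic:
        tx = pick_tx(primaries)
        i = int(rng.integers(0, len(tx.exons)))
        j = int(rng.integers(i, len(tx.exons)))
        d_start = int(rng.integers(*spec.near_offset, endpoint=True))
        d_end = int(rng.integers(*spec.near_offset, endpoint=True))
        start = tx.exons[i][0] - d_start
        end = tx.exons[j][1] + d_end
        if start >= 0 and add(tx.chrom, start, end, tx.strand, "circRNA"):
            n_done += 1
        guard = _bump(guard)

    n_done = 0
    while n_done < spec.n_ei:
        tx = pick_tx(primaries)
        i = int(rng.integers(0, len(tx.exons)))
        delta = int(rng.integers(*spec.ei_offset, endpoint=True))
        end = tx.exons[-1][1] + delta
        chrom_len = len(reference.genome[tx.chrom])
        if end < chrom_len and add(tx.chrom, tx.exons[i][0], end, tx.strand,
                                   "EI-circRNA"):
            n_done += 1
        guard = _bump(guard)

    n_done = 0
    while n_done < spec.n_cirna:
        tx = pick_tx(multi)
        i = int(rng.integers(0, len(tx.exons) - 1))
        intron = (tx.exons[i][1], tx.exons[i + 1][0])
        if intron[1] - intron[0] < 150:
            guard = _bump(guard)
            continue
        if add(tx.chrom, intron[0] + 50, intron[1] - 50, tx.strand, "ciRNA"):
            n_done += 1
        guard = _bump(guard)

    # free intergenic intervals, 100 bp clear of any gene span
    gaps: List[Tuple[str, int, int]] = []
    for chrom, seq in reference.genome.items():
        spans = sorted(
            (g.start, g.end) for g in model.genes.values() if g.chrom == chrom
        )
        prev = 0
        for g_start, g_end in spans:
            if g_start - prev >= 600:
                gaps.append((chrom, prev + 100, g_start - 100))
            prev = g_end
        if len(seq) - prev >= 600:
            gaps.append((chrom, prev + 100, len(seq) - 100))
    if spec.n_intergenic and not gaps:
        raise SpecError("no intergenic room for the requested plants")

    n_done = 0
    while n_done < spec.n_intergenic:
        chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        length = int(rng.integers(200, 401))
        if hi - lo <= length:
            guard = _bump(guard)
            continue
        start = lo + int(rng.integers(0, hi - lo - length))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if add(chrom, start, start + length, strand, "intergenic"):
            n_done += 1
        guard = _bump(guard)

    return records


def _bump(guard: int, limit: int = 100_000) -> int:
    if guard >= limit:
        raise SpecError("could not place requested truth records; relax the spec")
    return guard + 1


def write_truth_bed(records: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.label}\t0\t"
                f"{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# Caller outputs
# ---------------------------------------------------------------------------

def make_tool_calls(
    spec: FixtureSpec, truth: Sequence[TruthRecord]
) -> Dict[Tuple[str, str], List[CircRNACall]]:
    """Per (tool, sample) call lists: tp_count truth keys + fp_count decoys.

    False-positive keys are drawn clear of every truth key (and of each
    other), so planted precision and sensitivity are exact by construction.
    """
    if spec.tp_count > len(truth):
        raise SpecError(
            f"tp_count {spec.tp_count} exceeds truth size {len(truth)}"
        )
    truth_keys = {t.key for t in truth}
    chroms = sorted({t.chrom for t in truth})
    out: Dict[Tuple[str, str], List[CircRNACall]] = {}
    for s_idx, sample in enumerate(spec.samples):
        for t_idx, tool in enumerate(spec.tools):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 3, s_idx, t_idx])
            )
            picked = rng.choice(len(truth), size=spec.tp_count, replace=False)
            calls: List[CircRNACall] = []
            for idx in sorted(int(i) for i in picked):
                rec = truth[idx]
                reads = int(rng.integers(*spec.bsj_read_range, endpoint=True))
                calls.append(
                    CircRNACall(rec.chrom, rec.start, rec.end, rec.strand,
                                reads, tool, sample)
                )
            seen_fp: set = set()
            while len(seen_fp) < spec.fp_count:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, spec.chrom_length - 600))
                end = start + int(rng.integers(150, 501))
                key = (chrom, start, end)
                if key in truth_keys or key in seen_fp:
                    continue
                seen_fp.add(key)
                reads = int(rng.integers(*spec.bsj_read_range, endpoint=True))
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                calls.append(
                    CircRNACall(chrom, start, end, strand, reads, tool, sample)
                )
            out[(tool, sample)] = calls
    return out


def write_tool_outputs(
    calls: Mapping[Tuple[str, str], Sequence[CircRNACall]], outdir: str
) -> Dict[Tuple[str, str], str]:
    paths = {}
    for (tool, sample), tool_calls in calls.items():
        tool_dir = os.path.join(outdir, tool)
        os.makedirs(tool_dir, exist_ok=True)
        path = os.path.join(tool_dir, f"{sample}.txt")
        write_tool_output(list(tool_calls), path, tool)
        paths[(tool, sample)] = path
    return paths


# ---------------------------------------------------------------------------
# miRNA prediction outputs
# ---------------------------------------------------------------------------

@dataclass
class PlantedMRE:
    circ_id: str
    mirna_id: str
    site_type: str
    position: int


@dataclass
class MirnaFixture:
    mirnas: Dict[str, str]            # miRNA id -> mature sequence (RNA)
    sequences: Dict[str, str]         # circ id -> mature sequence with sites
    planted: List[PlantedMRE]
    miranda_hits: List[MirandaHit]
    targetscan_hits: List[TargetScanHit]


_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "T": "A"}
_DNA = {"A": "A", "C": "C", "G": "G", "U": "T", "T": "T"}


def _implant(seq: List[str], mirna: str, pos: int, site_type: str) -> None:
    """Overwrite target bases so exactly the requested site type sits at pos.

    Flanking bases are forced to non-matching values so a planted 6mer does
    not accidentally read as a 7mer/8mer.
    """
    mirna = mirna.upper().replace("T", "U")
    core = [
        _DNA[_RNA_COMPLEMENT[b]] for b in reversed(mirna[1:7])
    ]
    seq[pos:pos + 6] = core
    m8c = _DNA[_RNA_COMPLEMENT[mirna[7]]]
    non_m8 = "A" if m8c != "A" else "C"
    if site_type in ("8mer", "7mer-m8"):
        seq[pos - 1] = m8c
    else:
        seq[pos - 1] = non_m8
    seq[pos + 6] = "A" if site_type in ("8mer", "7mer-A1") else "C"


def make_mirna_outputs(
    spec: FixtureSpec, mature_sequences: Mapping[str, str]
) -> MirnaFixture:
    """Plant MRE sites and emit consistent miRanda/TargetScan hit sets.

    Planted (circRNA, miRNA) pairs appear in both outputs; decoy pairs are
    unique to one output each, so the algorithm intersection recovers exactly
    the planted pairs.
    """
    if not mature_sequences:
        raise SpecError("mature sequences required")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    mirnas = {
        f"fix-miR-{i + 1}": _random_seq(rng, spec.mirna_length,
                                        np.array(list("ACGU")))
        for i in range(spec.n_mirnas)
    }
    mirna_ids = list(mirnas)
    circ_ids = sorted(mature_sequences)
    seqs = {cid: list(mature_sequences[cid]) for cid in circ_ids}
    min_len = min(len(s) for s in seqs.values())
    if min_len < 30:
        raise SpecError("mature sequences too short to host planted sites")

    planted: List[PlantedMRE] = []
    used_pairs: set = set()
    slots: Dict[str, int] = {cid: 0 for cid in circ_ids}
    for k in range(spec.n_planted_pairs):
        cid = circ_ids[k % len(circ_ids)]
        mid = mirna_ids[k % len(mirna_ids)]
        if (cid, mid) in used_pairs:
            raise SpecError(
                "cannot plant distinct pairs: increase sequences or miRNAs"
            )
        used_pairs.add((cid, mid))
        pos = 2 + 12 * slots[cid]
        if pos + 8 > len(seqs[cid]):
            raise SpecError(f"sequence {cid} too short for another site")
        slots[cid] += 1
        site_type = SITE_TYPES[k % len(SITE_TYPES)]
        _implant(seqs[cid], mirnas[mid], pos, site_type)
        planted.append(PlantedMRE(cid, mid, site_type, pos))

    miranda_hits = [
        MirandaHit(p.circ_id, p.mirna_id,
                   float(np.round(rng.uniform(140, 180), 2)),
                   float(np.round(rng.uniform(-35, -21), 2)),
                   p.position)
        for p in planted
    ]
    targetscan_hits = [
        TargetScanHit(p.circ_id, p.mirna_id, p.site_type, p.position)
        for p in planted
    ]

    def fresh_pair() -> Tuple[str, str]:
        guard = 0
        while True:
            pair = (
                circ_ids[int(rng.integers(0, len(circ_ids)))],
                mirna_ids[int(rng.integers(0, len(mirna_ids)))],
            )
            if pair not in used_pairs:
                used_pairs.add(pair)
                return pair
            guard = _bump(guard, 10_000)

    for _ in range(spec.n_miranda_only):
        cid, mid = fresh_pair()
        miranda_hits.append(
            MirandaHit(cid, mid, float(np.round(rng.uniform(140, 180), 2)),
                       float(np.round(rng.uniform(-30, -10), 2)),
                       int(rng.integers(0, min_len - 8)))
        )
    for _ in range(spec.n_targetscan_only):
        cid, mid = fresh_pair()
        targetscan_hits.append(
            TargetScanHit(cid, mid, SITE_TYPES[int(rng.integers(0, 4))],
                          int(rng.integers(0, min_len - 8)))
        )

    return MirnaFixture(
        mirnas=mirnas,
        sequences={cid: "".join(chars) for cid, chars in seqs.items()},
        planted=planted,
        miranda_hits=miranda_hits,
        targetscan_hits=targetscan_hits,
    )


# ---------------------------------------------------------------------------
# Whole-directory emission
# ---------------------------------------------------------------------------

def generate_fixture_tree(spec: FixtureSpec, outdir: str) -> Dict[str, str]:
    """Emit the complete fixture directory and return the path map.

    Layout: genome.fa, annotation.gtf, truth.bed, <tool>/<sample>.txt,
    mirna/{miranda.txt,targetscan.txt,mature.fa,mirnas.fa}, spec.json.
    """
    os.makedirs(outdir, exist_ok=True)
    reference = make_reference(spec)
    truth = make_truth(spec, reference)

    genome_path = os.path.join(outdir, "genome.fa")
    write_fasta(reference.genome, genome_path)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    with open(gtf_path, "w") as handle:
        handle.write(reference.gtf_text)
    truth_path = os.path.join(outdir, "truth.bed")
    write_truth_bed(truth, truth_path)

    calls = make_tool_calls(spec, truth)
    paths = {
        "genome": genome_path,
        "gtf": gtf_path,
        "truth": truth_path,
    }
    for (tool, sample), path in write_tool_outputs(calls, outdir).items():
        paths[f"{tool}/{sample}"] = path

    # mature sequences for planted-MRE files come from the exonic truth set
    exonic = [t for t in truth if t.label == "circRNA"]
    if exonic:
        mature = {
            circ_id(t.chrom, t.start, t.end, t.strand):
                reference.genome[t.chrom][t.start:t.end][:400]
            for t in exonic
        }
        mirna_fix = make_mirna_outputs(spec, mature)
        mirna_dir = os.path.join(outdir, "mirna")
        os.makedirs(mirna_dir, exist_ok=True)
        paths["miranda"] = os.path.join(mirna_dir, "miranda.txt")
        write_miranda(mirna_fix.miranda_hits, paths["miranda"])
        paths["targetscan"] = os.path.join(mirna_dir, "targetscan.txt")
        write_targetscan(mirna_fix.targetscan_hits, paths["targetscan"])
        paths["mature"] = os.path.join(mirna_dir, "mature.fa")
        write_fasta(mirna_fix.sequences, paths["mature"])
        paths["mirnas"] = os.path.join(mirna_dir, "mirnas.fa")
        write_fasta(mirna_fix.mirnas, paths["mirnas"])

    spec_path = os.path.join(outdir, "spec.json")
    with open(spec_path, "w") as handle:
        json.dump(asdict(spec), handle, indent=2, sort_keys=True)
    paths["spec"] = spec_path
    return paths
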