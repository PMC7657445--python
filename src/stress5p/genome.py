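"""Toy genomes and transcript annotations.

The coordinate model follows the mapping strategy used for scanning-factor
CRAC data: reads are aligned to an intron-removed genome, so every transcript
is a single exon with contiguous 5'UTR / CDS / 3'UTR segments.  All intervals
are 0-based half-open genomic coordinates internally; GFF3 output converts to
the standard 1-based inclusive convention.

A :class:`GenomeBundle` may contain two species: the study organism
(*S. cerevisiae*-like) and a spike-in species (*S. pombe*-like) kept on
separate chromosomes, mirroring alignment to a concatenated two-species
genome for spike-in normalized RNA-seq.  Study chromosomes may additionally
carry rRNA-like "background" loci: highly bound, stress-insensitive features
that dominate real CRAC libraries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotatedTranscript:
    """A single-exon transcript with UTR/CDS structure.

    Intervals are 0-based half-open genomic coordinates.  In transcription
    order the segments are 5'UTR, CDS, 3'UTR; on the minus strand that means
    the 3'UTR occupies the lowest genomic coordinates.

    Parameters
    ----------
    id : unique transcript identifier
    species : ``"study"`` or ``"spike"``
    chrom, strand : placement on the genome
    utr5, cds, utr3 : ``(start, end)`` genomic intervals; UTRs may be empty
    regulon : ``"RP"``, ``"RiBi"`` or ``"other"`` -- coordinately regulated
        transcript classes used for decay summaries
    biotype : ``"mRNA"`` or ``"rRNA"``; rRNA-like loci model the stable,
        heavily crosslinked background of CRAC libraries
    """

    id: str
    species: str
    chrom: str
    strand: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    regulon: str = "other"
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.species not in ("study", "spike"):
            raise ValueError(f"bad species {self.species!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for name, (s, e) in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
            if s < 0 or e < s:
                raise ValueError(f"{self.id}: invalid {name} interval {(s, e)}")
        if self.cds_len < 3 or self.cds_len % 3:
            raise ValueError(f"{self.id}: CDS length {self.cds_len} not a positive multiple of 3")
        # transcription-order contiguity
        if self.strand == "+":
            order = (self.utr5, self.cds, self.utr3)
        else:
            order = (self.utr3, self.cds, self.utr5)
        for (_, e1), (s2, _) in zip(order, order[1:]):
            if e1 != s2:
                raise ValueError(f"{self.id}: segments not contiguous in transcription order")

    @property
    def utr5_len(self) -> int:
        return self.utr5[1] - self.utr5[0]

    @property
    def cds_len(self) -> int:
        return self.cds[1] - self.cds[0]

    @property
    def utr3_len(self) -> int:
        return self.utr3[1] - self.utr3[0]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the whole transcript."""
        segs = (self.utr5, self.cds, self.utr3)
        return min(s for s, _ in segs), max(e for _, e in segs)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    def offset_of(self, pos: int) -> int:
        """Transcript-coordinate offset (0 = first transcribed base) of a genomic position."""
        s, e = self.span
        if not s <= pos < e:
            raise ValueError(f"position {pos} outside {self.id}")
        return pos - s if self.strand == "+" else e - 1 - pos

    def genomic_pos(self, offset: int) -> int:
        """Genomic position of a transcript-coordinate offset."""
        s, e = self.span
        if not 0 <= offset < e - s:
            raise ValueError(f"offset {offset} outside {self.id}")
        return s + offset if self.strand == "+" else e - 1 - offset

    def fivep_region_len(self, cds_window: int = 150) -> int:
        """Length of the 5'-binding region: 5'UTR plus the first ``cds_window``
        nt of coding sequence (whole CDS when shorter)."""
        return self.utr5_len + min(cds_window, self.cds_len)


@dataclass
class GenomeBundle:
    """Chromosome sequences plus transcript annotations for one or two species."""

    chromosomes: dict[str, str]
    transcripts: list[AnnotatedTranscript]
    spike_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript ids in bundle")
        for t in self.transcripts:
            if t.chrom not in self.chromosomes:
                raise ValueError(f"{t.id}: unknown chromosome {t.chrom}")
            s, e = t.span
            if e > len(self.chromosomes[t.chrom]):
                raise ValueError(f"{t.id}: extends past end of {t.chrom}")
            on_spike = t.chrom in self.spike_chroms
            if on_spike != (t.species == "spike"):
                raise ValueError(f"{t.id}: species/chromosome assignment inconsistent")

    def get(self, transcript_id: str) -> AnnotatedTranscript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def transcript_seq(self, t: AnnotatedTranscript) -> str:
        """Transcript sequence in transcription (5'->3') order."""
        s, e = t.span
        seq = self.chromosomes[t.chrom][s:e]
        return seq if t.strand == "+" else revcomp(seq)

    @property
    def study_transcripts(self) -> list[AnnotatedTranscript]:
        return [t for t in self.transcripts if t.species == "study"]

    @property
    def spike_transcripts(self) -> list[AnnotatedTranscript]:
        return [t for t in self.transcripts if t.species == "spike"]

    @property
    def mrna_transcripts(self) -> list[AnnotatedTranscript]:
        return [t for t in self.transcripts if t.biotype == "mRNA"]

    @property
    def background_transcripts(self) -> list[AnnotatedTranscript]:
        return [t for t in self.transcripts if t.biotype == "rRNA"]


DEFAULT_LENGTH_PARAMS: dict[str, tuple[int, int]] = {
    "utr5": (20, 100),
    "cds": (300, 1500),
    "utr3": (30, 150),
    "spacer": (80, 200),
    "background": (4500, 5400),
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _draw_cds_len(rng: np.random.Generator, lo: int, hi: int) -> int:
    """A CDS length that is a multiple of 3 within [lo, hi]."""
    lo3 = -(-lo // 3) * 3
    hi3 = (hi // 3) * 3
    if hi3 < lo3 or lo3 < 3:
        raise ValueError(f"CDS length range ({lo}, {hi}) cannot yield a positive multiple of 3")
    return int(rng.integers(lo3 // 3, hi3 // 3 + 1)) * 3


def build_toy_genome(
    n_study: int,
    n_spike: int = 0,
    length_params: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    n_background: int = 0,
    rp_fraction: float = 0.10,
    ribi_fraction: float = 0.15,
) -> GenomeBundle:
    """Generate a random two-species toy genome with annotated transcripts.

    Study mRNAs are laid out on one chromosome, rRNA-like background loci
    (``n_background``) on a second study chromosome, and spike-in transcripts
    on a chromosome of the spike species.  A fraction of study mRNAs is
    labeled as the ribosomal-protein (RP) and ribosome-biogenesis (RiBi)
    regulons.  Deterministic for a given seed.
    """
    if n_study < 1:
        raise ValueError("n_study must be >= 1")
    if n_spike < 0 or n_background < 0:
        raise ValueError("counts must be non-negative")
    params = dict(DEFAULT_LENGTH_PARAMS)
    if length_params:
        params.update(length_params)
    rng = np.random.default_rng(seed)

    def _layout(n: int, chrom: str, species: str, prefix: str) -> tuple[str, list[AnnotatedTranscript]]:
        parts: list[str] = []
        txs: list[AnnotatedTranscript] = []
        cursor = 0
        for i in range(n):
            gap = int(rng.integers(*params["spacer"]))
            parts.append(_random_seq(rng, gap))
            cursor += gap
            u5 = int(rng.integers(params["utr5"][0], params["utr5"][1] + 1))
            cds = _draw_cds_len(rng, *params["cds"])
            u3 = int(rng.integers(params["utr3"][0], params["utr3"][1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            length = u5 + cds + u3
            parts.append(_random_seq(rng, length))
            s = cursor
            if strand == "+":
                utr5 = (s, s + u5)
                cdsi = (s + u5, s + u5 + cds)
                utr3 = (s + u5 + cds, s + length)
            else:
                utr3 = (s, s + u3)
                cdsi = (s + u3, s + u3 + cds)
                utr5 = (s + u3 + cds, s + length)
            txs.append(
                AnnotatedTranscript(
                    id=f"{prefix}{i + 1:04d}",
                    species=species,
                    chrom=chrom,
                    strand=strand,
                    utr5=utr5,
                    cds=cdsi,
                    utr3=utr3,
                )
            )
            cursor += length
        gap = int(rng.integers(*params["spacer"]))
        parts.append(_random_seq(rng, gap))
        return "".join(parts), txs

    chroms: dict[str, str] = {}
    transcripts: list[AnnotatedTranscript] = []

    seq, txs = _layout(n_study, "chrS1", "study", "SC_T")
    # regulon assignment over study mRNAs
    n_rp = int(round(rp_fraction * n_study))
    n_ribi = int(round(ribi_fraction * n_study))
    idx = rng.permutation(n_study)
    rp_ids = {txs[i].id for i in idx[:n_rp]}
    ribi_ids = {txs[i].id for i in idx[n_rp : n_rp + n_ribi]}
    txs = [
        dataclasses.replace(t, regulon="RP" if t.id in rp_ids else "RiBi" if t.id in ribi_ids else "other")
        for t in txs
    ]
    chroms["chrS1"] = seq
    transcripts.extend(txs)

    if n_background:
        parts: list[str] = []
        cursor = 0
        bg_txs: list[AnnotatedTranscript] = []
        for i in range(n_background):
            gap = int(rng.integers(*params["spacer"]))
            parts.append(_random_seq(rng, gap))
            cursor += gap
            cds = _draw_cds_len(rng, *params["background"])
            parts.append(_random_seq(rng, cds))
            bg_txs.append(
                AnnotatedTranscript(
                    id=f"SC_RRNA{i + 1:02d}",
                    species="study",
                    chrom="chrS_rDNA",
                    strand="+",
                    utr5=(cursor, cursor),
                    cds=(cursor, cursor + cds),
                    utr3=(cursor + cds, cursor + cds),
                    biotype="rRNA",
                )
            )
            cursor += cds
        parts.append(_random_seq(rng, int(rng.integers(*params["spacer"]))))
        chroms["chrS_rDNA"] = "".join(parts)
        transcripts.extend(bg_txs)

    spike_chroms: set[str] = set()
    if n_spike:
        seq, txs = _layout(n_spike, "chrP1", "spike", "SP_T")
        chroms["chrP1"] = seq
        transcripts.extend(txs)
        spike_chroms.add("chrP1")

    return GenomeBundle(chromosomes=chroms, transcripts=transcripts, spike_chroms=spike_chroms)


# ---------------------------------------------------------------------------
# I/O


def write_fasta(bundle: GenomeBundle, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(bundle.chromosomes.items())]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_gff3(bundle: GenomeBundle, path: str | Path) -> None:
    """Write transcripts as GFF3 (1-based inclusive) with
    five_prime_UTR / CDS / three_prime_UTR child features."""
    lines = ["##gff-version 3"]
    for name in sorted(bundle.chromosomes):
        lines.append(f"##sequence-region {name} 1 {len(bundle.chromosomes[name])}")
    feat_type = {"mRNA": "mRNA", "rRNA": "rRNA"}
    for t in sorted(bundle.transcripts, key=lambda t: (t.chrom, t.span[0], t.id)):
        s, e = t.span
        attrs = f"ID={t.id};species={t.species};regulon={t.regulon};biotype={t.biotype}"
        lines.append(
            "\t".join([t.chrom, "stress5p", feat_type[t.biotype], str(s + 1), str(e), ".", t.strand, ".", attrs])
        )
        for part, (ps, pe) in (("five_prime_UTR", t.utr5), ("CDS", t.cds), ("three_prime_UTR", t.utr3)):
            if pe > ps:
                lines.append(
                    "\t".join(
                        [t.chrom, "stress5p", part, str(ps + 1), str(pe), ".", t.strand,
                         "0" if part == "CDS" else ".", f"ID={t.id}:{part};Parent={t.id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeBundle:
    """Load a bundle back from FASTA + GFF3 written by :func:`write_fasta` /
    :func:`write_gff3` (or equivalently structured files)."""
    import gffutils
    from Bio import SeqIO

    chromosomes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: list[AnnotatedTranscript] = []
    spike_chroms: set[str] = set()
    for feat in db.all_features(featuretype=("mRNA", "rRNA")):
        tid = feat.id
        parts: dict[str, tuple[int, int]] = {}
        for child in db.children(feat):
            parts[child.featuretype] = (child.start - 1, child.end)
        cds = parts["CDS"]
        empty_5p = (cds[0], cds[0]) if feat.strand == "+" else (cds[1], cds[1])
        empty_3p = (cds[1], cds[1]) if feat.strand == "+" else (cds[0], cds[0])
        t = AnnotatedTranscript(
            id=tid,
            species=feat.attributes.get("species", ["study"])[0],
            chrom=feat.seqid,
            strand=feat.strand,
            utr5=parts.get("five_prime_UTR", empty_5p),
            cds=cds,
            utr3=parts.get("three_prime_UTR", empty_3p),
            regulon=feat.attributes.get("regulon", ["other"])[0],
            biotype=feat.featuretype,
        )
        transcripts.append(t)
        if t.species == "spike":
            spike_chroms.add(t.chrom)
    transcripts.sort(key=lambda t: (t.chrom, t.span[0], t.id))
    return GenomeBundle(chromosomes=chromosomes, transcripts=transcripts, spike_chroms=spike_chroms)
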