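"""Readers and writers for the formats the pipeline consumes.

Minimal VCF v4.2 (CHROM/POS/ID/REF/ALT + GT), two-channel TIFF or paired
PNG images, FASTA/FASTQ (gzip-aware), and TSV tables for phenotypes,
trials, and per-region outputs. Genome coordinates are 1-based inclusive;
pixel coordinates are 0-based (row, col).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .behavior import TrialCounts
from .gwas import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING, Variant)
from .popgen import HaplotypeMatrix
from .segmentation import R7Region, RetinaImage
from .synthetic import MosaicGroundTruth

__all__ = [
    "read_fasta", "read_fastq", "read_haplotype_vcf", "read_image_pair",
    "read_phenotype_tsv", "read_trials_tsv", "read_vcf",
    "write_fasta", "write_fastq", "write_ground_truth_json",
    "write_image", "write_phenotype_tsv", "write_regions_tsv",
    "write_trials_tsv", "write_vcf",
]

_GT_CODE = {"0/0": HOM_REF, "0|0": HOM_REF,
            "0/1": HET, "1/0": HET, "0|1": HET, "1|0": HET,
            "1/1": HOM_ALT, "1|1": HOM_ALT}
_CODE_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_CODE_GT_PHASED = {HOM_REF: "0|0", HOM_ALT: "1|1", MISSING: ".|."}


class VcfFormatError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_vcf(genotypes: GenotypeMatrix, path, phased: bool = False) -> None:
    """Minimal VCF v4.2 with GT-only sample columns."""
    code_map = _CODE_GT_PHASED if phased else _CODE_GT
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.lines) + "\n")
        for j, v in enumerate(genotypes.variants):
            gts = []
            for i in range(genotypes.n_lines):
                code = int(genotypes.calls[i, j])
                if phased and code == HET:
                    raise ValueError("cannot write heterozygous calls as "
                                     "phased without haplotype information")
                gts.append(code_map[code])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Parse a minimal VCF into a GenotypeMatrix.

    Only the GT subfield is consumed; any genotype other than 0/0, 0/1,
    1/1 (either separator) maps to MISSING. Malformed lines raise
    VcfFormatError with the line number.
    """
    variants: List[Variant] = []
    lines: Optional[List[str]] = None
    rows: List[List[int]] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                fields = raw.split("\t")
                if len(fields) < 10 or fields[8:9] != ["FORMAT"]:
                    raise VcfFormatError(path, line_no,
                                         "header must carry FORMAT and at "
                                         "least one sample column")
                lines = fields[9:]
                continue
            if lines is None:
                raise VcfFormatError(path, line_no,
                                     "data record before #CHROM header")
            fields = raw.split("\t")
            if len(fields) != 9 + len(lines):
                raise VcfFormatError(path, line_no,
                                     f"expected {9 + len(lines)} columns, "
                                     f"got {len(fields)}")
            chrom, pos, vid, ref, alt = fields[:5]
            try:
                pos_i = int(pos)
            except ValueError:
                raise VcfFormatError(path, line_no,
                                     f"non-integer POS {pos!r}") from None
            fmt_keys = fields[8].split(":")
            if "GT" not in fmt_keys:
                raise VcfFormatError(path, line_no, "record lacks GT")
            gt_idx = fmt_keys.index("GT")
            row = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                if len(alleles) != 2:
                    raise VcfFormatError(path, line_no,
                                         f"mixed or non-diploid ploidy in "
                                         f"GT {gt!r}")
                row.append(_GT_CODE.get(gt.replace("|", "/"), MISSING))
            variants.append(Variant(chrom, pos_i, ref, alt, vid=vid))
            rows.append(row)
    if lines is None:
        raise VcfFormatError(path, 0, "no #CHROM header found")
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.zeros((len(lines), 0), dtype=np.int8))
    return GenotypeMatrix(variants, lines, calls)


def write_haplotype_vcf(haps: HaplotypeMatrix, path, chrom: str = "3R",
                        ref: str = "A", alt: str = "AC") -> None:
    """Phased VCF from a haplotype matrix (consecutive pairs form samples).

    An odd trailing haplotype is dropped with a note in the sample count.
    The focal site is tagged ID=focal; all sites are written as the given
    ref/alt pair.
    """
    n_samples = haps.n_haps // 2
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(f"hap_pair_{i:03d}" for i in range(n_samples))
                 + "\n")
        for j in range(haps.n_sites):
            vid = "focal" if j == haps.focal_index else f"s{j}"
            gts = [f"{haps.haplotypes[2 * i, j]}|{haps.haplotypes[2 * i + 1, j]}"
                   for i in range(n_samples)]
            fh.write(f"{chrom}\t{haps.positions[j]}\t{vid}\t{ref}\t{alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_haplotype_vcf(path, focal: Optional[Tuple[str, int]] = None
                       ) -> HaplotypeMatrix:
    """Phased VCF -> HaplotypeMatrix (two haplotypes per sample).

    Unphased ("/") genotypes raise. The focal site is located by
    (chrom, pos) when given, else by ID == "focal".
    """
    positions: List[int] = []
    columns: List[List[int]] = []
    focal_index = None
    with _open_text(path) as fh:
        lines = None
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("##"):
                continue
            if raw.startswith("#CHROM"):
                lines = raw.split("\t")[9:]
                continue
            if lines is None:
                raise VcfFormatError(path, line_no,
                                     "data record before #CHROM header")
            fields = raw.split("\t")
            chrom, pos, vid = fields[0], int(fields[1]), fields[2]
            col = []
            for sample in fields[9:]:
                gt = sample.split(":")[0]
                if "|" not in gt:
                    raise VcfFormatError(path, line_no,
                                         f"haplotype mode requires phased "
                                         f"GT, got {gt!r}")
                a, b = gt.split("|")
                if a not in "01" or b not in "01":
                    raise VcfFormatError(path, line_no,
                                         f"non-binary or missing allele in "
                                         f"{gt!r}")
                col.extend([int(a), int(b)])
            if focal is not None and (chrom, pos) == focal:
                focal_index = len(positions)
            elif focal is None and vid == "focal":
                focal_index = len(positions)
            positions.append(pos)
            columns.append(col)
    if focal_index is None:
        raise ValueError("focal site not found in haplotype VCF")
    haps = np.array(columns, dtype=np.int8).T
    return HaplotypeMatrix(haps, np.array(positions), focal_index)


def write_image(image: RetinaImage, path, fmt: str = "tiff") -> None:
    """Two-channel float32 TIFF (channel axis first: rh3 then rh4)."""
    if fmt != "tiff":
        raise ValueError("only two-channel TIFF writing is supported")
    stack = np.stack([image.rh3, image.rh4]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_image_pair(path_or_paths, rh3_first: bool = True) -> RetinaImage:
    """Load a two-channel TIFF, or a pair of single-channel image files.

    Channel assignment is explicit via *rh3_first*; integer images are
    promoted to float in [0, 1] by their dtype range.
    """
    def _promote(arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr.astype(float) / np.iinfo(arr.dtype).max
        return arr.astype(float)

    if isinstance(path_or_paths, (list, tuple)):
        import imageio.v3 as iio
        a, b = (_promote(iio.imread(p)) for p in path_or_paths)
    else:
        stack = tifffile.imread(path_or_paths)
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise ValueError("expected a 2-channel TIFF (channel axis first)")
        a, b = _promote(stack[0]), _promote(stack[1])
    if a.shape != b.shape:
        raise ValueError(f"channel shape mismatch: {a.shape} vs {b.shape}")
    return RetinaImage(a, b) if rh3_first else RetinaImage(b, a)


def write_fasta(reads: Sequence[str], path, prefix: str = "read") -> None:
    records = [SeqRecord(Seq(r), id=f"{prefix}_{i}", description="")
               for i, r in enumerate(reads)]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> List[str]:
    with _open_text(path) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fasta")]


def write_fastq(reads: Sequence[str], path, prefix: str = "read",
                quality: int = 40) -> None:
    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(Seq(r), id=f"{prefix}_{i}", description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(r)
        records.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> List[str]:
    with _open_text(path) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def write_phenotype_tsv(phenotype: pd.Series, path) -> None:
    df = phenotype.rename("pct_on").rename_axis("line_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"line_id", "pct_on"} <= set(df.columns):
        raise ValueError("phenotype TSV needs line_id and pct_on columns")
    return df.set_index("line_id")["pct_on"]


def write_trials_tsv(trials: Sequence[TrialCounts], path) -> None:
    df = pd.DataFrame({
        "line_id": [t.line_id for t in trials],
        "genotype": ["sin" if t.has_insertion else "no_sin"
                     if t.has_insertion is not None else ""
                     for t in trials],
        "n_green": [t.n_green for t in trials],
        "n_blue": [t.n_blue for t in trials],
    })
    df.to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> List[TrialCounts]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    needed = {"line_id", "n_green", "n_blue"}
    if not needed <= set(df.columns):
        raise ValueError(f"trial TSV needs columns {sorted(needed)}")
    trials = []
    for _, row in df.iterrows():
        geno = str(row.get("genotype", ""))
        has_ins = {"sin": True, "no_sin": False}.get(geno)
        trials.append(TrialCounts(int(row["n_green"]), int(row["n_blue"]),
                                  line_id=str(row["line_id"]),
                                  has_insertion=has_ins))
    return trials


def write_regions_tsv(regions: Sequence[R7Region], path) -> None:
    df = pd.DataFrame({
        "label": [r.label for r in regions],
        "centroid_row": [r.centroid[0] for r in regions],
        "centroid_col": [r.centroid[1] for r in regions],
        "area": [r.pixel_count for r in regions],
        "mean_rh3": [r.mean_rh3 for r in regions],
        "mean_rh4": [r.mean_rh4 for r in regions],
        "call": [r.call for r in regions],
    })
    df.to_csv(path, sep="\t", index=False)


def write_ground_truth_json(truth: MosaicGroundTruth, path) -> None:
    payload = {
        "centers": truth.centers.tolist(),
        "identities": truth.identities.astype(int).tolist(),
        "is_border": truth.is_border.astype(int).tolist(),
        "on_fraction_true": truth.on_fraction_true,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
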