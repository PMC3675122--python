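"""Readers and writers for the file formats the pipeline touches.

PLINK bed/bim/fam (SNP-major binary), Beagle-style phased haplotype text
plus a markers sidecar, a dosage VCF with DS/GP (and phased GT) fields,
tab-separated classical-typing files and aligned allele-sequence tables.
Coordinates are 1-based inclusive throughout; the genome build is treated
as metadata only.

Genotype values in PLINK tables count the A1 allele of each variant; in
panel/dosage outputs encoded markers use the symbolic alleles ``P``
(presence) / ``A`` (absence) with the marker id in the VCF ID column.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import AlleleSequence, BinaryMarker, HlaTyping, GENES, sort_markers
from .panel import ReferencePanel

__all__ = [
    "read_plink",
    "write_plink",
    "read_typings",
    "write_typings",
    "read_sequences",
    "write_sequences",
    "write_reference_panel",
    "read_reference_panel",
    "write_dosage_vcf",
    "write_dosage_table",
]

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, SNP-major: 00 = hom A1 (dosage 2), 01 = missing,
# 10 = het (1), 11 = hom A2 (0)
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: float("nan"), 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_plink(prefix: str):
    """Read a PLINK bed/bim/fam trio.

    Returns ``(geno, bim, fam)``: genotypes as an individuals x SNPs
    DataFrame of A1-allele counts (NaN missing), and the .bim/.fam tables.
    Rejects bad magic bytes and truncated SNP blocks.
    """
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "position", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "status"],
        dtype={"fid": str, "iid": str},
    )
    n, s = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"{prefix}.bed: bad magic bytes {magic!r} (not a SNP-major bed file)"
            )
        data = fh.read()
    bpv = math.ceil(n / 4)
    if len(data) != bpv * s:
        raise ValueError(
            f"{prefix}.bed: truncated or oversized payload at byte offset "
            f"{3 + len(data)} (expected {bpv * s} genotype bytes)"
        )
    raw = np.frombuffer(data, dtype=np.uint8).reshape(s, bpv)
    # unpack 2-bit codes, individual-minor within each byte (LSB first)
    codes = np.empty((s, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    geno = lut[codes].T  # individuals x snps
    return (
        pd.DataFrame(geno, index=fam["iid"].tolist(), columns=bim["id"].tolist()),
        bim,
        fam,
    )


def write_plink(prefix: str, geno: pd.DataFrame, bim: pd.DataFrame,
                fam: pd.DataFrame | None = None) -> None:
    """Write a PLINK bed/bim/fam trio (SNP-major).  ``geno`` counts the A1
    allele; ``bim`` needs columns id/position/a1/a2 (chrom defaults to 6)."""
    n, s = geno.shape
    if list(geno.columns) != list(bim["id"]):
        raise ValueError("bim ids do not match genotype columns")
    if fam is None:
        fam = pd.DataFrame(
            {"fid": geno.index, "iid": geno.index, "father": 0, "mother": 0,
             "sex": 0, "status": -9}
        )
    if len(fam) != n:
        raise ValueError("fam rows do not match genotype individuals")
    chrom = bim["chrom"] if "chrom" in bim else pd.Series(["6"] * s)
    cm = bim["cm"] if "cm" in bim else pd.Series([0] * s)
    with open(f"{prefix}.bim", "w") as fh:
        for i in range(s):
            fh.write(
                f"{chrom.iloc[i]}\t{bim['id'].iloc[i]}\t{cm.iloc[i]}\t"
                f"{bim['position'].iloc[i]}\t{bim['a1'].iloc[i]}\t{bim['a2'].iloc[i]}\n"
            )
    with open(f"{prefix}.fam", "w") as fh:
        for r in fam.itertuples(index=False):
            fh.write(f"{r.fid}\t{r.iid}\t{r.father}\t{r.mother}\t{r.sex}\t{r.status}\n")
    mat = geno.to_numpy(dtype=float)
    bpv = math.ceil(n / 4)
    out = np.zeros((s, bpv), dtype=np.uint8)
    codes = np.full((s, n), 0b01, dtype=np.uint8)  # missing
    for dose, code in _DOSAGE_TO_CODE.items():
        codes[mat.T == dose] = code
    for k in range(4):
        chunk = codes[:, k::4]
        out[:, :chunk.shape[1]] |= chunk.astype(np.uint8) << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


# ---------------------------------------------------------------------------
# typings and sequences
# ---------------------------------------------------------------------------

def write_typings(path: str, typings: Sequence[HlaTyping]) -> None:
    """Tab-separated typing file: one row per individual, two columns per
    gene (missing calls written as NA)."""
    genes = sorted({t.gene for t in typings}, key=GENES.index)
    by_ind: dict[str, dict[str, HlaTyping]] = {}
    order: list[str] = []
    for t in typings:
        if t.individual not in by_ind:
            order.append(t.individual)
        by_ind.setdefault(t.individual, {})[t.gene] = t
    with open(path, "w") as fh:
        cols = ["ID"] + [f"{g}_{i}" for g in genes for i in (1, 2)]
        fh.write("\t".join(cols) + "\n")
        for ind in order:
            row = [ind]
            for g in genes:
                t = by_ind[ind].get(g)
                row.append(t.allele1 if t and t.allele1 else "NA")
                row.append(t.allele2 if t and t.allele2 else "NA")
            fh.write("\t".join(row) + "\n")


def read_typings(path: str) -> list[HlaTyping]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "ID":
        raise ValueError(f"{path}: first column must be ID")
    genes = []
    for c in df.columns[1:]:
        g = c.rsplit("_", 1)[0]
        if g not in genes:
            genes.append(g)
    out: list[HlaTyping] = []
    for r in df.itertuples(index=False):
        ind = r[0]
        for gi, g in enumerate(genes):
            a1 = r[1 + 2 * gi]
            a2 = r[2 + 2 * gi]
            a1 = None if pd.isna(a1) or a1 in ("NA", "0") else a1
            a2 = None if pd.isna(a2) or a2 in ("NA", "0") else a2
            out.append(HlaTyping(ind, g, a1, a2))
    return out


def write_sequences(path: str, sequences: Sequence[AlleleSequence]) -> None:
    """Aligned allele-sequence table: gene / allele / residue string / start
    position of the alignment frame (gap ``-``, termination ``*``)."""
    with open(path, "w") as fh:
        fh.write("gene\tallele\tsequence\tstart\n")
        for s in sequences:
            fh.write(f"{s.gene}\t{s.allele}\t{s.residues}\t{s.positions[0]}\n")


def read_sequences(path: str) -> list[AlleleSequence]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "allele": str,
                                            "sequence": str})
    out = []
    for r in df.itertuples(index=False):
        start = int(getattr(r, "start", 1))
        seq = r.sequence
        positions = tuple(range(start, start + len(seq)))
        out.append(AlleleSequence(r.gene, r.allele, seq, positions))
    return out


# ---------------------------------------------------------------------------
# phased panel text
# ---------------------------------------------------------------------------

def write_reference_panel(prefix: str, panel: ReferencePanel) -> None:
    """Beagle-style phased text (``I id`` header row, one ``M`` row per
    marker with two allele columns per individual) plus a markers sidecar
    (id, kind, gene, position, allele codes, frequency)."""
    with open(f"{prefix}.bgl.phased", "w") as fh:
        header = ["I", "id"]
        for ind in panel.individuals:
            header += [ind, ind]
        fh.write(" ".join(header) + "\n")
        freqs = panel.frequencies()
        for j, m in enumerate(panel.markers):
            row = ["M", m.id]
            col = panel.haplotypes[:, j]
            row += [m.present_label if v else m.absent_label for v in col]
            fh.write(" ".join(row) + "\n")
    with open(f"{prefix}.markers.tsv", "w") as fh:
        fh.write("id\tkind\tgene\tposition\tpresent\tabsent\tfrequency\n")
        for m, f in zip(panel.markers, freqs):
            fh.write(
                f"{m.id}\t{m.kind}\t{m.gene}\t{m.position}\t"
                f"{m.present_label}\t{m.absent_label}\t{f:.6g}\n"
            )


def read_reference_panel(prefix: str,
                         window=(29_000_000, 34_000_000)) -> ReferencePanel:
    mdf = pd.read_csv(f"{prefix}.markers.tsv", sep="\t",
                      dtype={"gene": str, "present": str, "absent": str})
    mdf["gene"] = mdf["gene"].fillna("")

    def _info(mid: str, kind: str, gene: str) -> dict:
        # the naming convention is invertible enough to restore the payload
        parts = mid.split("_")
        if kind in ("HLA4", "HLA2"):
            return {"allele": f"{gene}*{parts[2]}"}
        if kind == "AA":
            return {"position": int(parts[2]), "residue": parts[4]}
        if kind == "INDEL":
            return {"position": int(parts[2])}
        return {}

    markers = [
        BinaryMarker(id=r.id, kind=r.kind, gene=r.gene, position=int(r.position),
                     present_label=r.present, absent_label=r.absent,
                     frequency=float(r.frequency),
                     info=_info(r.id, r.kind, r.gene))
        for r in mdf.itertuples(index=False)
    ]
    by_id = {m.id: m for m in markers}
    with open(f"{prefix}.bgl.phased") as fh:
        header = fh.readline().split()
        if header[:2] != ["I", "id"]:
            raise ValueError(f"{prefix}.bgl.phased: missing 'I id' header")
        hap_names = header[2:]
        individuals = hap_names[::2]
        if hap_names[1::2] != individuals:
            raise ValueError("phased header must list each individual twice")
        rows = []
        order = []
        for line in fh:
            parts = line.split()
            if parts[0] != "M":
                raise ValueError(f"unexpected row type {parts[0]!r}")
            mid = parts[1]
            m = by_id.get(mid)
            if m is None:
                raise ValueError(f"marker {mid!r} missing from sidecar")
            alleles = parts[2:]
            rows.append([1 if a == m.present_label else 0 for a in alleles])
            order.append(m)
    haps = np.asarray(rows, dtype=np.uint8).T
    ordered = sort_markers(order)
    if [m.id for m in ordered] != [m.id for m in order]:
        idx = {m.id: i for i, m in enumerate(order)}
        haps = haps[:, [idx[m.id] for m in ordered]]
        order = ordered
    return ReferencePanel(haps, order, individuals, window)


# ---------------------------------------------------------------------------
# dosage outputs
# ---------------------------------------------------------------------------

def write_dosage_table(path: str, result) -> None:
    """Tab-separated dosage file: marker, alleles, one dosage column per
    individual."""
    with open(path, "w") as fh:
        fh.write("marker\tpresent\tabsent\t" + "\t".join(result.individuals) + "\n")
        dosage = result.dosage
        for m in result.markers:
            vals = "\t".join(f"{v:.4f}" for v in dosage[m.id])
            fh.write(f"{m.id}\t{m.present_label}\t{m.absent_label}\t{vals}\n")


def write_dosage_vcf(path: str, result, chrom: str = "6") -> None:
    """VCF 4.2 with phased GT, DS (alternate-allele dosage) and GP fields.

    Encoded markers are emitted as biallelic records with symbolic alleles
    (absence = REF, presence = ALT) and the marker id in ID; the ALT allele
    of every record is the "present" allele, so DS = GP1 + 2*GP2.
    """
    n = len(result.individuals)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess phased genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(result.individuals) + "\n")
        for j, m in enumerate(result.markers):
            if m.kind == "SNP":
                ref, alt = m.absent_label, m.present_label
            else:
                ref, alt = "A", "P"
            fields = []
            for i in range(n):
                gt = f"{result.hap_calls[i, 0, j]}|{result.hap_calls[i, 1, j]}"
                ds = result.dosage.iat[i, j]
                gp = result.gp[i, j]
                fields.append(
                    f"{gt}:{ds:.4f}:{gp[0]:.4f},{gp[1]:.4f},{gp[2]:.4f}"
                )
            fh.write(
                f"{chrom}\t{m.position}\t{m.id}\t{ref}\t{alt}\t.\tPASS\t.\t"
                "GT:DS:GP\t" + "\t".join(fields) + "\n"
            )
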