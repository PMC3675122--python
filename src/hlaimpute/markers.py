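"""Binary presence/absence encoding of classical HLA alleles, amino acid
residues and indel events.

The HLA loci are highly multi-allelic: a single gene can carry dozens of
classical alleles and an aligned protein position can carry several residues.
To let a biallelic haplotype model (and a standard 1-degree-of-freedom
association test) handle this variation uniformly, every allele of every
multi-allelic variant is recoded as its own binary presence/absence marker:

* ``HLA4`` / ``HLA2`` -- one marker per distinct 4-digit / 2-digit classical
  allele of a gene (e.g. ``HLA_A_0101``);
* ``AA`` -- one marker per residue observed at a polymorphic aligned
  amino acid position (a position with three residues yields three markers);
* ``INDEL`` -- one marker per distinct insertion/deletion/truncation event
  seen in the protein alignment;
* ``SNP`` -- ordinary biallelic SNPs pass through unchanged.

An individual's genotype at a marker is the count (0/1/2) of that allele
among their two chromosomes, so within a gene the classical-allele dosages
of a fully typed individual sum to exactly 2, and likewise per aligned
position for residue dosages (at gap-free positions).

All markers are anchored at genomic coordinates (per-gene anchor plus a
3 bp-per-codon offset for residue markers) so the combined SNP + encoded
marker set has a total genomic order, which the haplotype HMM requires.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENES",
    "DEFAULT_GENE_ANCHORS",
    "HlaTyping",
    "AlleleSequence",
    "BinaryMarker",
    "parse_allele",
    "reduce_resolution",
    "encode_classical_alleles",
    "encode_amino_acids",
    "encode_indels",
    "decode_classical",
    "allele_block_vectors",
    "residue_dosage_from_typings",
]

#: HLA genes handled by the encoder (class I and class II).
GENES = ("A", "B", "C", "DPA1", "DPB1", "DQA1", "DQB1", "DRB1")

#: Default per-gene anchor coordinates on chr6 (bp, 1-based), approximating
#: the physical gene locations inside the 29-34 Mb MHC window.  Overridable
#: wherever an ``anchors`` mapping is accepted.
DEFAULT_GENE_ANCHORS: dict[str, int] = {
    "A": 29_910_000,
    "C": 31_240_000,
    "B": 31_320_000,
    "DRB1": 32_550_000,
    "DQA1": 32_610_000,
    "DQB1": 32_660_000,
    "DPA1": 33_040_000,
    "DPB1": 33_050_000,
}

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
TERM = "*"

_ALLELE_RE = re.compile(r"^([A-Z][A-Z0-9]*)\*(\d{2}|\d{4})$")


def parse_allele(label: str) -> tuple[str, str]:
    """Split a classical allele label like ``"A*0101"`` into (gene, digits).

    Raises ``ValueError`` for labels that do not parse or name an unknown gene.
    """
    m = _ALLELE_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable HLA allele label: {label!r}")
    gene, digits = m.group(1), m.group(2)
    if gene not in GENES:
        raise ValueError(f"unknown HLA gene {gene!r} in allele label {label!r}")
    return gene, digits


def allele_resolution(label: str) -> int:
    """Return 2 or 4 for a classical allele label."""
    _, digits = parse_allele(label)
    return len(digits)


def reduce_resolution(label: str, return_flag: bool = False):
    """Reduce a 4-digit allele label to its 2-digit family label.

    ``"B*0702" -> "B*07"``.  A 2-digit input is returned unchanged; with
    ``return_flag=True`` a second boolean reports whether the input was
    already at 2-digit resolution.  Deterministic and idempotent.
    """
    gene, digits = parse_allele(label)
    already = len(digits) == 2
    out = label if already else f"{gene}*{digits[:2]}"
    return (out, already) if return_flag else out


@dataclass(frozen=True)
class HlaTyping:
    """Gold-standard classical typing of one individual at one gene.

    ``allele1``/``allele2`` are labels at 2- or 4-digit resolution, or
    ``None`` for an explicit missing call.
    """

    individual: str
    gene: str
    allele1: str | None
    allele2: str | None

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"unknown HLA gene {self.gene!r}")
        for a in (self.allele1, self.allele2):
            if a is not None:
                g, _ = parse_allele(a)
                if g != self.gene:
                    raise ValueError(
                        f"allele {a!r} does not match typing gene {self.gene!r}"
                    )

    def resolved_pair(self, resolution: int) -> tuple[str, str] | None:
        """Both alleles at the requested resolution, or ``None`` if either
        allele is missing or only typed more coarsely than requested."""
        out = []
        for a in (self.allele1, self.allele2):
            if a is None:
                return None
            if resolution == 2:
                out.append(reduce_resolution(a))
            else:
                if allele_resolution(a) < 4:
                    return None
                out.append(a)
        return out[0], out[1]


@dataclass(frozen=True)
class AlleleSequence:
    """Aligned protein sequence of one 4-digit classical allele.

    ``residues`` is a string over the amino acid alphabet plus ``-`` (gap)
    and ``*`` (termination); all alleles of a gene share one alignment frame.
    ``positions`` maps aligned offsets to protein positions (1-based; may be
    negative for the leader peptide); defaults to 1..L.
    """

    gene: str
    allele: str
    residues: str
    positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        g, digits = parse_allele(self.allele)
        if g != self.gene:
            raise ValueError(f"allele {self.allele!r} does not match gene {self.gene!r}")
        if len(digits) != 4:
            raise ValueError(f"allele sequences must be 4-digit: {self.allele!r}")
        bad = set(self.residues) - AA_ALPHABET - {GAP, TERM}
        if bad:
            raise ValueError(
                f"residue symbol(s) {sorted(bad)} outside alphabet in {self.allele!r}"
            )
        if self.positions is None:
            object.__setattr__(
                self, "positions", tuple(range(1, len(self.residues) + 1))
            )
        elif len(self.positions) != len(self.residues):
            raise ValueError(
                f"positions/residues length mismatch for {self.allele!r}"
            )

    def events(self) -> list[tuple]:
        """Indel events carried by this allele: maximal gap runs as
        ``("del", start_position, length)`` and the first termination symbol
        as ``("trunc", position)``."""
        ev: list[tuple] = []
        j = 0
        L = len(self.residues)
        while j < L:
            if self.residues[j] == GAP:
                j0 = j
                while j < L and self.residues[j] == GAP:
                    j += 1
                ev.append(("del", self.positions[j0], j - j0))
            elif self.residues[j] == TERM:
                ev.append(("trunc", self.positions[j]))
                break
            else:
                j += 1
        return ev


@dataclass
class BinaryMarker:
    """One presence/absence variable placed at a genomic coordinate.

    ``kind`` is one of ``SNP``, ``HLA2``, ``HLA4``, ``AA``, ``INDEL``.
    ``present_label``/``absent_label`` name the two "alleles" of the binary
    recoding (nucleotides for SNPs, ``P``/``A`` for encoded markers).
    ``info`` carries the defining payload (allele label, residue, event),
    used to reconstruct per-allele marker vectors.
    """

    id: str
    kind: str
    gene: str
    position: int
    present_label: str = "P"
    absent_label: str = "A"
    frequency: float = float("nan")
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("SNP", "HLA2", "HLA4", "AA", "INDEL"):
            raise ValueError(f"unknown marker kind {self.kind!r}")


def _marker_sort_key(m: BinaryMarker):
    return (m.position, m.id)


def sort_markers(markers: Iterable[BinaryMarker]) -> list[BinaryMarker]:
    return sorted(markers, key=_marker_sort_key)


def _check_typings(typings: Sequence[HlaTyping]) -> None:
    if not typings:
        raise ValueError("typings collection is empty")
    seen = set()
    for t in typings:
        key = (t.individual, t.gene)
        if key in seen:
            raise ValueError(f"duplicate typing for individual/gene {key}")
        seen.add(key)


def _individual_order(typings: Sequence[HlaTyping]) -> list[str]:
    order: list[str] = []
    seen = set()
    for t in typings:
        if t.individual not in seen:
            seen.add(t.individual)
            order.append(t.individual)
    return order


def _frequencies(geno: pd.DataFrame) -> pd.Series:
    n_chrom = 2.0 * geno.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        return geno.sum(axis=0, skipna=True) / n_chrom


def encode_classical_alleles(
    typings: Sequence[HlaTyping],
    resolution: int = 4,
    anchors: Mapping[str, int] | None = None,
    partial_policy: str = "missing",
):
    """Encode classical typings as one binary marker per distinct allele.

    Returns ``(markers, genotypes, report)`` where ``genotypes`` is an
    individual x marker DataFrame of allele counts (NaN where the individual
    is not fully resolved at the requested resolution) and ``report`` lists
    partially typed individuals per gene.

    ``partial_policy`` handles individuals not resolvable at ``resolution``:
    ``"missing"`` sets their dosages at that gene's markers to NaN,
    ``"drop"`` removes them from the genotype table entirely.
    """
    if resolution not in (2, 4):
        raise ValueError("resolution must be 2 or 4")
    if partial_policy not in ("missing", "drop"):
        raise ValueError("partial_policy must be 'missing' or 'drop'")
    _check_typings(typings)
    anchors = dict(anchors or DEFAULT_GENE_ANCHORS)
    kind = "HLA4" if resolution == 4 else "HLA2"

    individuals = _individual_order(typings)
    labels: dict[str, set[str]] = {}
    partial: dict[str, list[str]] = {}
    rows: dict[tuple[str, str], tuple[str, str] | None] = {}
    for t in typings:
        pair = t.resolved_pair(resolution)
        rows[(t.individual, t.gene)] = pair
        if pair is None:
            partial.setdefault(t.gene, []).append(t.individual)
        else:
            labels.setdefault(t.gene, set()).update(pair)
    if not labels:
        raise ValueError(
            f"no individual is callable at {resolution}-digit resolution"
        )
    if partial_policy == "drop":
        dropped = {i for inds in partial.values() for i in inds}
        individuals = [i for i in individuals if i not in dropped]
        if not individuals:
            raise ValueError("all individuals dropped by partial_policy='drop'")

    markers: list[BinaryMarker] = []
    for gene in sorted(labels):
        if gene not in anchors:
            raise ValueError(f"no anchor coordinate configured for gene {gene!r}")
        for lab in sorted(labels[gene]):
            _, digits = parse_allele(lab)
            markers.append(
                BinaryMarker(
                    id=f"HLA_{gene}_{digits}",
                    kind=kind,
                    gene=gene,
                    position=anchors[gene],
                    info={"allele": lab},
                )
            )
    ids = [m.id for m in markers]
    geno = pd.DataFrame(np.nan, index=individuals, columns=ids)
    col_of = {m.info["allele"]: m.id for m in markers}
    for (ind, gene), pair in rows.items():
        if ind not in geno.index:
            continue
        gene_cols = [m.id for m in markers if m.gene == gene]
        if pair is None:
            continue  # stays NaN
        geno.loc[ind, gene_cols] = 0.0
        for a in pair:
            geno.loc[ind, col_of[a]] += 1.0
    freqs = _frequencies(geno)
    for m in markers:
        m.frequency = float(freqs[m.id])
    report = {"partial_individuals": partial, "resolution": resolution}
    return markers, geno, report


def _sequence_map(
    sequences: Sequence[AlleleSequence],
) -> dict[str, dict[str, AlleleSequence]]:
    by_gene: dict[str, dict[str, AlleleSequence]] = {}
    for s in sequences:
        gmap = by_gene.setdefault(s.gene, {})
        if s.allele in gmap:
            raise ValueError(f"duplicate sequence for allele {s.allele!r}")
        gmap[s.allele] = s
    for gene, gmap in by_gene.items():
        lengths = {a: len(s.residues) for a, s in gmap.items()}
        if len(set(lengths.values())) > 1:
            off = min(lengths, key=lambda a: lengths[a])
            raise ValueError(
                f"sequence length mismatch within gene {gene!r} "
                f"(e.g. allele {off!r}); all alleles must share one alignment frame"
            )
        frames = {s.positions for s in gmap.values()}
        if len(frames) > 1:
            raise ValueError(f"inconsistent position frames within gene {gene!r}")
    return by_gene


def _observed_alleles(
    typings: Sequence[HlaTyping],
    seqmap: Mapping[str, Mapping[str, AlleleSequence]],
    on_unmappable: str,
):
    """4-digit alleles observed per gene, and per-individual resolved pairs.

    Individuals whose pair includes an allele without a sequence are treated
    per ``on_unmappable``: ``"raise"`` aborts naming the allele, ``"report"``
    leaves them missing and lists the alleles.
    """
    observed: dict[str, set[str]] = {}
    pairs: dict[tuple[str, str], tuple[str, str] | None] = {}
    unmappable: dict[str, set[str]] = {}
    for t in typings:
        pair = t.resolved_pair(4)
        if pair is not None:
            missing_seq = [
                a for a in pair if a not in seqmap.get(t.gene, {})
            ]
            if missing_seq:
                if on_unmappable == "raise":
                    raise ValueError(
                        f"no aligned sequence for observed allele(s) "
                        f"{missing_seq} at gene {t.gene!r}"
                    )
                unmappable.setdefault(t.gene, set()).update(missing_seq)
                pair = None
        if pair is not None:
            observed.setdefault(t.gene, set()).update(pair)
        pairs[(t.individual, t.gene)] = pair
    return observed, pairs, unmappable


def encode_amino_acids(
    sequences: Sequence[AlleleSequence],
    typings: Sequence[HlaTyping],
    anchors: Mapping[str, int] | None = None,
    on_unmappable: str = "raise",
):
    """Encode polymorphic aligned amino acid positions as binary markers.

    For every aligned position with >=2 distinct symbols among the observed
    alleles, one ``AA`` marker is emitted per amino acid residue at that
    position (gap/termination symbols are handled by :func:`encode_indels`).
    An individual's dosage at a residue marker is the number of their two
    classical alleles carrying that residue; monomorphic positions emit
    nothing.
    """
    _check_typings(typings)
    anchors = dict(anchors or DEFAULT_GENE_ANCHORS)
    seqmap = _sequence_map(sequences)
    observed, pairs, unmappable = _observed_alleles(typings, seqmap, on_unmappable)

    individuals = _individual_order(typings)
    markers: list[BinaryMarker] = []
    columns: list[np.ndarray] = []
    for gene in sorted(observed):
        alleles = sorted(observed[gene])
        gmap = seqmap[gene]
        L = len(next(iter(gmap.values())).residues)
        positions = next(iter(gmap.values())).positions
        seq_arr = {a: gmap[a].residues for a in alleles}
        for j in range(L):
            symbols = {seq_arr[a][j] for a in alleles}
            if len(symbols) < 2:
                continue
            residues = sorted(symbols & AA_ALPHABET)
            pos = positions[j]
            for res in residues:
                bp = anchors[gene] + 3 * pos
                markers.append(
                    BinaryMarker(
                        id=f"AA_{gene}_{pos}_{bp}_{res}",
                        kind="AA",
                        gene=gene,
                        position=bp,
                        info={
                            "position": pos,
                            "aligned_index": j,
                            "residue": res,
                            "alleles": [a for a in alleles if seq_arr[a][j] == res],
                        },
                    )
                )
                col = np.full(len(individuals), np.nan)
                for i, ind in enumerate(individuals):
                    pair = pairs.get((ind, gene))
                    if pair is None:
                        continue
                    col[i] = sum(1.0 for a in pair if seq_arr[a][j] == res)
                columns.append(col)
    ids = [m.id for m in markers]
    geno = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(individuals), 0)),
        index=individuals,
        columns=ids,
    )
    freqs = _frequencies(geno)
    for m in markers:
        m.frequency = float(freqs[m.id])
    report = {"unmappable_alleles": {g: sorted(s) for g, s in unmappable.items()}}
    return markers, geno, report


def encode_indels(
    sequences: Sequence[AlleleSequence],
    typings: Sequence[HlaTyping],
    anchors: Mapping[str, int] | None = None,
    on_unmappable: str = "raise",
):
    """Encode gap runs and truncations in the protein alignment as binary
    markers, one per distinct event (a 2-residue deletion is one event and
    therefore one marker)."""
    _check_typings(typings)
    anchors = dict(anchors or DEFAULT_GENE_ANCHORS)
    seqmap = _sequence_map(sequences)
    observed, pairs, unmappable = _observed_alleles(typings, seqmap, on_unmappable)

    individuals = _individual_order(typings)
    markers: list[BinaryMarker] = []
    columns: list[np.ndarray] = []
    for gene in sorted(observed):
        alleles = sorted(observed[gene])
        gmap = seqmap[gene]
        events: dict[tuple, list[str]] = {}
        for a in alleles:
            for ev in gmap[a].events():
                events.setdefault(ev, []).append(a)
        used_ids: set[str] = set()
        for ev in sorted(events, key=lambda e: (e[1], e[0], e[2:] or (0,))):
            pos = ev[1]
            bp = anchors[gene] + 3 * pos
            mid = f"INDEL_{gene}_{pos}_{bp}"
            k = 1
            while mid in used_ids:  # two distinct events at one position
                k += 1
                mid = f"INDEL_{gene}_{pos}_{bp}_{k}"
            used_ids.add(mid)
            carriers = set(events[ev])
            markers.append(
                BinaryMarker(
                    id=mid,
                    kind="INDEL",
                    gene=gene,
                    position=bp,
                    info={"event": ev, "alleles": sorted(carriers)},
                )
            )
            col = np.full(len(individuals), np.nan)
            for i, ind in enumerate(individuals):
                pair = pairs.get((ind, gene))
                if pair is None:
                    continue
                col[i] = sum(1.0 for a in pair if a in carriers)
            columns.append(col)
    ids = [m.id for m in markers]
    geno = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(individuals), 0)),
        index=individuals,
        columns=ids,
    )
    freqs = _frequencies(geno)
    for m in markers:
        m.frequency = float(freqs[m.id])
    report = {"unmappable_alleles": {g: sorted(s) for g, s in unmappable.items()}}
    return markers, geno, report


def decode_classical(
    geno: pd.DataFrame, markers: Sequence[BinaryMarker]
) -> list[HlaTyping]:
    """Invert a 4-digit classical genotype table back to typings.

    Each individual's allele multiset per gene is recovered from the HLA4
    dosage counts (the encoding is invertible at 4-digit resolution).
    """
    by_gene: dict[str, list[BinaryMarker]] = {}
    for m in markers:
        if m.kind == "HLA4" and m.id in geno.columns:
            by_gene.setdefault(m.gene, []).append(m)
    out: list[HlaTyping] = []
    for ind in geno.index:
        for gene, ms in sorted(by_gene.items()):
            row = geno.loc[ind, [m.id for m in ms]]
            if row.isna().any():
                out.append(HlaTyping(ind, gene, None, None))
                continue
            alleles: list[str] = []
            for m in ms:
                alleles.extend([m.info["allele"]] * int(round(row[m.id])))
            if len(alleles) != 2:
                raise ValueError(
                    f"gene {gene!r} dosages for {ind!r} do not sum to 2"
                )
            out.append(HlaTyping(ind, gene, alleles[0], alleles[1]))
    return out


def allele_block_vectors(
    markers: Sequence[BinaryMarker],
    sequences: Sequence[AlleleSequence] | None = None,
) -> dict[str, tuple[list[str], dict[str, np.ndarray]]]:
    """Per-gene haplotype vectors of every 4-digit allele over the gene's
    encoded markers (HLA4 + HLA2 + AA + INDEL).

    Used to project phased haplotypes onto logically consistent one-hot
    configurations and to build haplotype-level truth in simulations.
    Returns ``{gene: (marker_ids, {allele: 0/1 vector})}``.
    """
    seqmap = _sequence_map(sequences) if sequences else {}
    by_gene: dict[str, list[BinaryMarker]] = {}
    for m in markers:
        if m.kind in ("HLA4", "HLA2", "AA", "INDEL"):
            by_gene.setdefault(m.gene, []).append(m)
    out: dict[str, tuple[list[str], dict[str, np.ndarray]]] = {}
    for gene, ms in by_gene.items():
        ms = sort_markers(ms)
        ids = [m.id for m in ms]
        alleles = sorted(
            m.info["allele"] for m in ms if m.kind == "HLA4"
        )
        gmap = seqmap.get(gene, {})
        vecs: dict[str, np.ndarray] = {}
        for a in alleles:
            v = np.zeros(len(ms), dtype=np.uint8)
            a2 = reduce_resolution(a)
            ev = set(gmap[a].events()) if a in gmap else set()
            for i, m in enumerate(ms):
                if m.kind == "HLA4":
                    v[i] = 1 if m.info["allele"] == a else 0
                elif m.kind == "HLA2":
                    v[i] = 1 if m.info["allele"] == a2 else 0
                elif m.kind == "AA":
                    if a in gmap:
                        j = m.info["aligned_index"]
                        v[i] = 1 if gmap[a].residues[j] == m.info["residue"] else 0
                elif m.kind == "INDEL":
                    v[i] = 1 if m.info["event"] in ev else 0
            vecs[a] = v
        out[gene] = (ids, vecs)
    return out


def residue_dosage_from_typings(
    typings: Sequence[HlaTyping],
    sequences: Sequence[AlleleSequence],
    gene: str,
    position: int,
    residue: str,
) -> pd.Series:
    """True dosage (0/1/2) of ``residue`` at protein ``position`` of ``gene``
    per individual, computed directly from classical typings."""
    seqmap = _sequence_map(sequences)
    gmap = seqmap.get(gene, {})
    if not gmap:
        raise ValueError(f"no sequences for gene {gene!r}")
    positions = next(iter(gmap.values())).positions
    try:
        j = positions.index(position)
    except ValueError:
        raise ValueError(f"position {position} not in alignment frame of {gene!r}")
    vals: dict[str, float] = {}
    for t in typings:
        if t.gene != gene:
            continue
        pair = t.resolved_pair(4)
        if pair is None or any(a not in gmap for a in pair):
            vals[t.individual] = np.nan
            continue
        vals[t.individual] = float(
            sum(1 for a in pair if gmap[a].residues[j] == residue)
        )
    return pd.Series(vals, name=f"AA_{gene}_{position}_{residue}")
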