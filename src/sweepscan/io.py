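"""Readers and writers for the standard formats the pipeline touches.

VCF is read through cyvcf2 and written by a small deterministic text writer
(the writer exists for round-tripping and for emitting simulated data; it is
not a general-purpose VCF library).  GTF gene models are read through
gffutils.  FASTA ``.fai`` indexes, two-column sample->population maps and
Newick trees are plain text.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import (
    MISSING,
    ChromLengths,
    GeneModel,
    GenotypeMatrix,
    chrom_sort_key,
)


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


# ---------------------------------------------------------------------------
# sample -> population map
# ---------------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample id and population label."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'sample<TAB>population'")
        if parts[0] in out:
            raise ValueError(f"{path}:{ln}: duplicate sample id {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def write_pop_map(pops: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in pops.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    population_map: dict[str, str],
    *,
    multiallelic: str = "drop",
) -> GenotypeMatrix:
    """Read GT dosages from a VCF into a :class:`GenotypeMatrix`.

    Dosage encodes the alternate-allele count: 0/0 -> 0; 0/1, 1/0 (or phased
    equivalents) -> 1; 1/1 -> 2; ./. -> MISSING.  Phase is ignored.

    Parameters
    ----------
    multiallelic
        ``"drop"`` (default) discards records with more than one ALT allele;
        ``"split"`` emits one biallelic record per ALT allele, with dosage
        counting that allele only.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in population_map]
    if absent:
        raise ValueError(
            f"samples missing from population map: {absent[:5]}"
            + ("..." if len(absent) > 5 else "")
        )

    chroms: list[str] = []
    pos: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str | None] = []
    cols: list[np.ndarray] = []
    for rec_no, v in enumerate(vcf, start=1):
        try:
            alt_alleles = v.ALT
            if not alt_alleles:
                continue
            if len(alt_alleles) == 1:
                gt = np.asarray(v.gt_types, dtype=np.int16)  # 0,1,2; 3=unknown
                gt[gt == 3] = MISSING
                per_alt = [(alt_alleles[0], gt)]
            elif multiallelic == "drop":
                continue
            else:
                per_alt = _split_multiallelic(v, alt_alleles)
            for alt, dos in per_alt:
                if alt == v.REF or not alt or alt in (".", "*"):
                    continue
                chroms.append(str(v.CHROM))
                pos.append(int(v.POS))
                refs.append(str(v.REF))
                alts.append(str(alt))
                ids.append(None if v.ID in (None, ".") else str(v.ID))
                cols.append(dos)
        except VcfParseError:
            raise
        except Exception as e:  # malformed record
            raise VcfParseError(f"{path}: record {rec_no}: {e}") from e

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": refs, "alt": alts, "id": ids}
    )
    dosage = (
        np.column_stack(cols)
        if cols
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    gm = GenotypeMatrix(
        samples=samples,
        pops={s: population_map[s] for s in samples},
        variants=variants,
        dosage=dosage,
    )
    return gm.sort_variants()


def _split_multiallelic(v, alt_alleles) -> list[tuple[str, np.ndarray]]:
    """Per-ALT dosage columns from a multi-allelic record's GT calls."""
    geno = v.genotypes  # [[a0, a1, phased], ...]
    out = []
    for ai, alt in enumerate(alt_alleles, start=1):
        dos = np.empty(len(geno), dtype=np.int16)
        for i, g in enumerate(geno):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise VcfParseError(f"non-diploid GT at {v.CHROM}:{v.POS}")
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for a in alleles if a == ai)
        out.append((str(alt), dos))
    return out


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    *,
    chrom_lengths: ChromLengths | None = None,
    extra_header: Iterable[str] = (),
) -> None:
    """Write a minimal deterministic GT-only VCF (debug/simulation writer)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        if chrom_lengths:
            for c in sorted(chrom_lengths, key=chrom_sort_key):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        variants = gm.variants
        for j in range(gm.n_variants):
            row = variants.iloc[j]
            vid = "." if row["id"] in (None, "") or pd.isna(row["id"]) else row["id"]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene features from a GTF (Ensembl dialect) as GeneModels.

    Coordinates are kept 1-based inclusive, as in the file.  Files with no
    gene features yield an empty list (with a warning).
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for f in db.features_of_type("gene", order_by=None):
        gene_id = (f.attributes.get("gene_id") or [f.id])[0]
        gene_name = (f.attributes.get("gene_name") or [gene_id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=str(f.seqid),
                start=int(f.start),
                end=int(f.end),
                strand=f.strand if f.strand in ("+", "-") else "+",
            )
        )
    if not genes:
        warnings.warn(f"{path}: no gene features found", stacklevel=2)
    return genes


# ---------------------------------------------------------------------------
# FASTA index
# ---------------------------------------------------------------------------

def read_fai(path: str | Path) -> ChromLengths:
    """Read chromosome lengths from a samtools ``.fai`` index.

    Only the first two columns (name, length) are consumed.
    """
    out = ChromLengths()
    n_rows = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least name and length")
        name = parts[0]
        if name in out:
            raise ValueError(f"{path}:{ln}: duplicate sequence name {name!r}")
        out[name] = int(parts[1])
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no sequences")
    return out


def sscrofa11_chrom_lengths() -> ChromLengths:
    """Chromosome lengths of the Sus scrofa 11.1 assembly (chr1-18 + X).

    Packaged as a ``.fai``-formatted fixture; only the name and length
    columns are meaningful (offset/linebases columns are placeholders).
    """
    res = importlib.resources.files("sweepscan.data") / "sscrofa11_1.fai"
    with importlib.resources.as_file(res) as p:
        return read_fai(p)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree, *, name_escape: str = "underscore") -> str:
    """Serialize a :class:`~sweepscan.structure.TreeNode` to Newick.

    ``name_escape`` controls leaf names containing whitespace: "underscore"
    replaces runs of whitespace with "_"; "quote" wraps the name in single
    quotes.
    """
    def esc(name: str) -> str:
        if any(ch.isspace() for ch in name):
            if name_escape == "quote":
                return "'" + name.replace("'", "''") + "'"
            return "_".join(name.split())
        return name

    def render(node) -> str:
        if not node.children:
            return esc(node.name or "")
        inner = ",".join(
            f"{render(child)}:{length:.10g}" for child, length in node.children
        )
        return f"({inner})" + (esc(node.name) if node.name else "")

    return render(tree) + ";"


def write_newick(tree, path: str | Path, *, name_escape: str = "underscore") -> None:
    """Write a tree with branch lengths as a Newick file."""
    Path(path).write_text(newick_string(tree, name_escape=name_escape) + "\n")
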