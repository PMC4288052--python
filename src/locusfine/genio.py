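"""Readers and writers for the genotype, probability, and phenotype formats.

Supported formats: text PED/MAP pairs, VCF v4.x (GT only, biallelic),
Oxford GEN genotype-probability tables, and TSV phenotype / result tables.
Coordinates are 1-based inclusive throughout.  After reading, genotypes are
oriented to count the minor allele over the full sample (cases and
controls); orientation is idempotent so write -> read round-trips are
identities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    AssociationResult,
    GenotypeMatrix,
    GenotypeProbabilities,
    SampleRecord,
    VariantRecord,
    neglog10,
)


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------------
# Minor-allele orientation
# ----------------------------------------------------------------------

def orient_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip variants so counts refer to the less frequent allele.

    A variant is flipped when the counted allele's frequency exceeds 0.5,
    or — at an exact 0.5 tie — when the counted allele sorts before the
    other one, giving a canonical choice that makes orientation idempotent.
    """
    out = gm.copy()
    freqs = out.allele_frequencies()
    for j, v in enumerate(out.variants):
        f = freqs[j]
        flip = f > 0.5 or (f == 0.5 and v.alt < v.ref)
        if flip:
            col = out.calls[:, j]
            nonmiss = col != MISSING
            col[nonmiss] = 2 - col[nonmiss]
            v.ref, v.alt = v.alt, v.ref
            f = 1.0 - f
        v.maf = float(min(f, 1.0 - f)) if np.isfinite(f) else float("nan")
    return out


# ----------------------------------------------------------------------
# PED / MAP
# ----------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
# PED phenotype: 1 = control, 2 = case
_PHENO_OUT = {0: "1", 1: "2"}


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.samples):
            fields = [s.id, s.id, "0", "0", _SEX_OUT.get(s.sex, "0"), _PHENO_OUT.get(s.status, "0")]
            for j, v in enumerate(gm.variants):
                g = gm.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [v.ref, v.ref]
                elif g == 1:
                    fields += [v.ref, v.alt]
                else:
                    fields += [v.alt, v.alt]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    variants = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 MAP columns")
            variants.append(VariantRecord(id=parts[1], chrom=parts[0], pos=int(parts[3])))
    V = len(variants)

    samples, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * V:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * V} fields, got {len(parts)}"
                )
            status = 1 if parts[5] == "2" else 0
            samples.append(
                SampleRecord(id=parts[1], sex=_SEX_CODE.get(parts[4], "unknown"), status=status)
            )
            rows.append((ln, parts[6:]))

    calls = np.full((len(samples), V), MISSING, dtype=np.int8)
    alleles: list[list[str]] = [[] for _ in range(V)]
    for j in range(V):
        seen: dict[str, int] = {}
        for (ln, allele_fields) in rows:
            for a in (allele_fields[2 * j], allele_fields[2 * j + 1]):
                if a != "0":
                    seen[a] = seen.get(a, 0) + 1
        if len(seen) > 2:
            raise FormatError(
                f"{ped_path}: variant {variants[j].id} is not biallelic "
                f"(alleles {sorted(seen)})"
            )
        # count the rarer allele; deterministic tie-break by allele symbol
        ordered = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ordered) == 0:
            variants[j].ref, variants[j].alt = "A", "G"
            continue
        if len(ordered) == 1:
            minor, major = "?", ordered[0][0]
        else:
            minor, major = ordered[0][0], ordered[1][0]
        variants[j].ref, variants[j].alt = major, minor
        for i, (ln, allele_fields) in enumerate(rows):
            a1, a2 = allele_fields[2 * j], allele_fields[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == minor) + (a2 == minor)
    gm = GenotypeMatrix(calls, variants, samples)
    return orient_minor(gm)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=3>\n##contig=<ID=AIM>\n")
        ids = "\t".join(s.id for s in gm.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        gt_map = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(gm.variants):
            gts = "\t".join(gt_map[int(g)] for g in gm.calls[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = [SampleRecord(id=s) for s in vcf.samples]
    variants, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"{path}: {rec.ID or rec.POS} is not biallelic")
        if "GT" not in rec.FORMAT:
            raise FormatError(f"{path}: record {rec.ID or rec.POS} lacks a GT field")
        g = rec.gt_types.astype(np.int8)  # 0,1,2 alt count; 3 = unknown
        g[g == 3] = MISSING
        cols.append(g)
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
    calls = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    return orient_minor(GenotypeMatrix(calls, variants, samples))


# ----------------------------------------------------------------------
# Oxford GEN probabilities
# ----------------------------------------------------------------------

def write_gen(probs: GenotypeProbabilities, path) -> None:
    with open(path, "w") as fh:
        for j, v in enumerate(probs.variants):
            head = f"{v.chrom} {v.id} {v.pos} {v.ref} {v.alt}"
            vals = " ".join(f"{p:.6g}" for p in probs.triplets[:, j, :].ravel())
            fh.write(f"{head} {vals}\n")


def read_gen_probs(path, samples: list[SampleRecord] | None = None) -> GenotypeProbabilities:
    variants, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if (len(parts) - 5) % 3 != 0:
                raise FormatError(f"{path}:{ln}: expected 3 probability columns per sample")
            variants.append(
                VariantRecord(
                    id=parts[1], chrom=parts[0], pos=int(parts[2]),
                    ref=parts[3], alt=parts[4], genotyped=False,
                )
            )
            vals = np.array(parts[5:], dtype=float)
            if (vals < 0).any():
                raise FormatError(f"{path}:{ln}: negative probability")
            trip = vals.reshape(-1, 3)
            sums = trip.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-3:
                raise FormatError(f"{path}:{ln}: probability triplets do not sum to 1")
            rows.append(trip / sums[:, None])
    if not rows:
        raise FormatError(f"{path}: empty probability file")
    n = rows[0].shape[0]
    if samples is None:
        samples = [SampleRecord(id=f"S{i + 1:06d}") for i in range(n)]
    t = np.stack(rows, axis=1)  # (samples, variants, 3)
    return GenotypeProbabilities(t, variants, list(samples))


# ----------------------------------------------------------------------
# Phenotype and result tables
# ----------------------------------------------------------------------

PHENO_COLUMNS = ["id", "sex", "status", "pc1", "pc2", "pc3", "admix1", "admix2", "admix3"]


def write_phenotypes(samples: list[SampleRecord], path) -> None:
    rows = []
    for s in samples:
        adm = s.admixture or (np.nan, np.nan, np.nan)
        pcs = s.pcs or (np.nan, np.nan, np.nan)
        rows.append([s.id, s.sex, s.status, pcs[0], pcs[1], pcs[2], adm[0], adm[1], adm[2]])
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleRecord(
                id=str(r["id"]),
                sex=str(r["sex"]),
                status=int(r["status"]),
                pcs=(float(r["pc1"]), float(r["pc2"]), float(r["pc3"])),
                admixture=(float(r["admix1"]), float(r["admix2"]), float(r["admix3"])),
            )
        )
    return out


RESULT_COLUMNS = [
    "variant_id", "model", "beta", "se", "or", "ci95_low", "ci95_high",
    "p", "neglog10_p", "n_eff", "conditioned_on", "note",
]


def write_results(results: list[AssociationResult] | pd.DataFrame, path) -> pd.DataFrame:
    """Write association results as TSV with a -log10(p) column.

    Storing the log-scale p alongside keeps extreme significance readable
    even when the raw p would print as 0.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
        df["neglog10_p"] = [neglog10(p) for p in df["p"]]
    df.to_csv(path, sep="\t", index=False)
    return df


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
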