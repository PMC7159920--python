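"""Readers and writers for the plain-text interchange formats.

Genotypes travel as PLINK text ``.ped``/``.map`` or additive-dosage
``.raw``-style tables; phenotypes and covariates as PLINK-dialect
whitespace tables (FID IID columns first); pedigrees, spouse pairs and
score weights as TSV.  GRMs use the GCTA binary triple
(``.grm.bin``/``.grm.N.bin``/``.grm.id``) or a gzipped text lower
triangle.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "write_plink", "write_raw", "read_raw",
    "write_phen", "read_phen",
    "write_pedigree", "read_pedigree",
    "write_spouses", "read_spouses",
    "write_weights", "read_weights",
    "write_gcta_grm", "read_gcta_grm",
    "write_grm_text", "read_grm_text",
]


# ---------------------------------------------------------------- genotypes
def write_plink(cohort, prefix: str | Path) -> None:
    """Write text PLINK ``.ped`` and ``.map`` files."""
    prefix = Path(prefix)
    v = cohort.variants
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    eff = v["effect_allele"].to_numpy()
    oth = v["other_allele"].to_numpy()
    ind = cohort.individuals
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(cohort.n_individuals):
            d = cohort.dosages[i]
            a1 = np.where(d >= 1, eff, oth)
            a2 = np.where(d == 2, eff, oth)
            geno = " ".join(f"{x} {y}" for x, y in zip(a1, a2))
            r = ind.iloc[i]
            fh.write(
                f"{r['id']} {r['id']} {r['father_id'] or 0} {r['mother_id'] or 0} "
                f"{r['sex']} -9 {geno}\n"
            )


def write_raw(cohort, path: str | Path) -> None:
    """Additive-dosage table (PLINK ``.raw`` dialect: counts of the effect allele)."""
    ind = cohort.individuals
    head = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{vid}_{a}" for vid, a in zip(cohort.variants["id"], cohort.variants["effect_allele"])
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(head) + "\n")
        for i in range(cohort.n_individuals):
            r = ind.iloc[i]
            fh.write(
                f"{r['id']} {r['id']} {r['father_id'] or 0} {r['mother_id'] or 0} "
                f"{r['sex']} -9 " + " ".join(map(str, cohort.dosages[i])) + "\n"
            )


def read_raw(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a ``.raw`` dosage table -> (sample frame, dosage matrix, variant ids)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise DataError(f".raw table missing columns: {missing}")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[snp_cols].to_numpy(dtype=float)
    ids = [c.rsplit("_", 1)[0] for c in snp_cols]
    return df[meta_cols], dosages, ids


# ---------------------------------------------------------------- tables
def write_phen(cohort, path: str | Path, traits: list[str] | None = None) -> None:
    """PLINK ``.phen``-style whitespace table: FID IID trait columns."""
    traits = traits or ["trait_a", "trait_b", "control"]
    out = pd.DataFrame({"FID": cohort.ids, "IID": cohort.ids})
    for t in traits:
        out[t] = cohort.phenos[t].to_numpy()
    out.to_csv(path, sep=" ", index=False)


def read_phen(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise DataError("phenotype table needs FID, IID and at least one trait column")
    return df


def write_pedigree(cohort, path: str | Path) -> None:
    ind = cohort.individuals
    pd.DataFrame(
        {
            "child": ind["id"],
            "mother": ind["mother_id"],
            "father": ind["father_id"],
            "sex": ind["sex"],
            "generation": ind["generation"],
            "subpop": ind["subpop"],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"child": str, "mother": str, "father": str})


def write_spouses(cohort, path: str | Path) -> None:
    rows = []
    for gen, pairs in sorted(cohort.spouse_pairs_by_gen.items()):
        rows.extend({"father": f, "mother": m, "generation": gen} for f, m in pairs)
    pd.DataFrame(rows, columns=["father", "mother", "generation"]).to_csv(
        path, sep="\t", index=False
    )


def read_spouses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"father": str, "mother": str})


def write_weights(cohort, path: str | Path) -> None:
    if cohort.effects is None:
        raise DataError("cohort has no effect set to export")
    cohort.effects.weights_frame(cohort.variants).to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"variant", "effect_allele"}
    if not need.issubset(df.columns):
        raise DataError(f"weight table must contain columns {sorted(need)}")
    return df


# ---------------------------------------------------------------- GRM
def write_gcta_grm(grm, prefix: str | Path) -> None:
    """GCTA binary triple: float32 lower triangle, per-pair SNP counts, id file."""
    prefix = Path(prefix)
    n = len(grm.ids)
    il, jl = np.tril_indices(n)
    grm.values[il, jl].astype("<f4").tofile(f"{prefix}.grm.bin")
    np.asarray(grm.n_snps_per_pair, dtype=float)[il, jl].astype("<f4").tofile(
        f"{prefix}.grm.N.bin"
    )
    pd.DataFrame({"FID": grm.ids, "IID": grm.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str | Path):
    from .varcomp import GRMatrix

    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].astype(str).tolist()
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise DataError("GRM binary size does not match id count")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    il, jl = np.tril_indices(n)
    vals = np.zeros((n, n))
    vals[il, jl] = tri
    vals[jl, il] = tri
    nmat = np.zeros((n, n))
    nmat[il, jl] = counts
    nmat[jl, il] = counts
    return GRMatrix(ids=ids, values=vals, n_snps_per_pair=nmat.astype(int))


def write_grm_text(grm, path: str | Path) -> None:
    """Gzipped text lower triangle: i j n_snps value (1-based indices)."""
    n = len(grm.ids)
    with gzip.open(path, "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(
                    f"{i + 1}\t{j + 1}\t{int(grm.n_snps_per_pair[i, j])}\t"
                    f"{grm.values[i, j]:.6g}\n"
                )


def read_grm_text(path: str | Path, ids: list[str]):
    from .varcomp import GRMatrix

    n = len(ids)
    vals = np.zeros((n, n))
    nmat = np.zeros((n, n), dtype=int)
    with gzip.open(path, "rt") as fh:
        for line in fh:
            i, j, cnt, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            vals[i, j] = vals[j, i] = float(v)
            nmat[i, j] = nmat[j, i] = int(cnt)
    return GRMatrix(ids=list(ids), values=vals, n_snps_per_pair=nmat)
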