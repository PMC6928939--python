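"""Readers and writers for the text formats the pipeline exchanges.

Genotypes travel as the PLINK-style .ped/.map text dialect (one sample
per .ped row: FID IID PAT MAT SEX PHENO followed by two allele letters
per variant, ``0 0`` for a missing call; one variant per .map row:
chromosome, id, genetic distance, 1-based bp position) or as a plain
TSV dosage matrix (samples x variants, NA for missing). Phenotypes and
result tables are TSV; truth records, QC reports and partitions are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_json",
    "read_json",
]


# ----------------------------------------------------------------------
# .ped/.map
# ----------------------------------------------------------------------
def write_ped_map(G: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns both paths.

    Dosage d counts copies of allele ``a2``: 0 -> ``a1 a1``, 1 ->
    ``a1 a2``, 2 -> ``a2 a2``, missing -> ``0 0``. Sex column: 1 male,
    2 female.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    vm = G.variant_meta
    with open(map_path, "w") as fh:
        for _, row in vm.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")

    a1 = vm["a1"].to_numpy()
    a2 = vm["a2"].to_numpy()
    # genotype word per (variant, dosage-class)
    words = np.empty((G.n_variants, 4), dtype=object)
    words[:, 0] = [f"{x} {x}" for x in a1]
    words[:, 1] = [f"{x} {y}" for x, y in zip(a1, a2)]
    words[:, 2] = [f"{y} {y}" for y in a2]
    words[:, 3] = "0 0"
    cls = np.where(np.isnan(G.dosages), 3, G.dosages).astype(int)
    col_idx = np.arange(G.n_variants)
    with open(ped_path, "w") as fh:
        for i in range(G.n_samples):
            sid = G.sample_meta["sample"].iloc[i]
            sex = 1 if G.sample_meta["reported_sex"].iloc[i] == "M" else 2
            geno = " ".join(words[col_idx, cls[i]])
            fh.write(f"{sid} {sid} 0 0 {sex} -9 {geno}\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read ``<prefix>.ped`` + ``<prefix>.map`` into a GenotypeMatrix.

    The minor allele (dosage-counted) is taken as the less frequent
    allele per variant; ties keep the alphabetically later letter, and
    monomorphic variants count the absent allele of the pair seen.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, snp, _, pos = parts[:4]
            map_rows.append((chrom, snp, int(pos)))
    m = len(map_rows)

    sample_ids: list[str] = []
    sexes: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            sample_ids.append(parts[1])
            sexes.append("M" if parts[4] == "1" else "F")
            allele_rows.append(np.array(parts[6:], dtype=object))
    alleles = np.array(allele_rows, dtype=object)  # n x 2m
    n = len(sample_ids)

    dosages = np.empty((n, m), dtype=float)
    a1_list, a2_list = [], []
    for j in range(m):
        pair = alleles[:, 2 * j : 2 * j + 2]
        flat = pair.ravel()
        seen = sorted({x for x in flat if x != "0"})
        if not seen:
            a1, a2 = "A", "B"
        elif len(seen) == 1:
            other = "B" if seen[0] != "B" else "A"
            a1, a2 = seen[0], other
        else:
            counts = {a: int((flat == a).sum()) for a in seen}
            minc = min(counts.values())
            a2 = max(a for a in seen if counts[a] == minc)  # minor allele
            a1 = next(a for a in seen if a != a2)
        miss = (pair == "0").any(axis=1)
        d = (pair == a2).sum(axis=1).astype(float)
        d[miss] = np.nan
        dosages[:, j] = d
        a1_list.append(a1)
        a2_list.append(a2)

    variant_meta = pd.DataFrame(
        {
            "snp": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "a1": a1_list,
            "a2": a2_list,
            "is_x": [r[0] in ("X", "23") for r in map_rows],
        }
    )
    sample_meta = pd.DataFrame({"sample": sample_ids, "reported_sex": sexes})
    return GenotypeMatrix(dosages, variant_meta, sample_meta)


# ----------------------------------------------------------------------
# TSV dosage matrix
# ----------------------------------------------------------------------
def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> Path:
    """Samples x variants dosage TSV plus a ``.variants.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        G.dosages,
        index=pd.Index(G.sample_ids, name="sample"),
        columns=G.variant_ids,
    )
    df.insert(0, "reported_sex", G.sample_meta["reported_sex"].to_numpy())
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    G.variant_meta.to_csv(
        path.with_suffix(".variants.tsv"), sep="\t", index=False
    )
    return path


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sexes = df.pop("reported_sex")
    vm = pd.read_csv(path.with_suffix(".variants.tsv"), sep="\t")
    vm["chrom"] = vm["chrom"].astype(str)
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        variant_meta=vm,
        sample_meta=pd.DataFrame(
            {"sample": df.index.astype(str), "reported_sex": sexes.to_numpy()}
        ),
    )


# ----------------------------------------------------------------------
# phenotypes / JSON
# ----------------------------------------------------------------------
def write_phenotypes(P: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    P.data.to_csv(path, sep="\t")
    return path


def read_phenotypes(path: str | Path, roi_columns: list[str] | None = None) -> PhenotypeTable:
    """Read a phenotype TSV; ROI columns default to everything after ``icv``."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    if roi_columns is None:
        cols = list(data.columns)
        roi_columns = cols[cols.index("icv") + 1 :]
    return PhenotypeTable(data, list(roi_columns))


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
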