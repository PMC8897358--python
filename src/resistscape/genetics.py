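"""Genotype tables and pairwise Weir–Cockerham Fst.

Diploid biallelic SNP genotypes are held as an individuals × loci matrix
of allele dosages (0, 1, 2; NaN for missing) with a population label per
individual. Pairwise population differentiation is the Weir & Cockerham
(1984) theta, combined across loci as a ratio of sums of the per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals):

    theta = sum_l a_l / sum_l (a_l + b_l + c_l)

Negative pairwise estimates are retained (truncating them to zero would
distort the downstream regression response); the count of negatives is
reported in the output metadata.

Two input dialects are supported:

* ``genalex-simplified`` — a Genalex-style CSV: row 1 holds
  ``n_loci, n_samples, n_pops`` followed by per-population sizes; row 2 a
  free-text title; row 3 the column header ``Sample, Pop`` then one locus
  name per pair of allele columns. Data rows carry two allele codes per
  locus, ``1`` (reference) / ``2`` (alternate), ``0`` = missing.
* ``dosage-csv`` — columns ``sample, pop`` then one column per locus with
  dosages 0/1/2, empty or ``NA`` = missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "write_genalex",
    "pairwise_fst",
]


@dataclass
class GenotypeMatrix:
    """Individuals × loci allele-dosage matrix with population labels."""

    dosages: np.ndarray            # (n_ind, n_loci) float, NaN = missing
    populations: np.ndarray        # (n_ind,) labels
    locus_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.populations = np.asarray(self.populations)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if len(self.populations) != self.dosages.shape[0]:
            raise ValueError("one population label per individual required")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.dosages.shape[0])]

    @property
    def pop_ids(self) -> list:
        seen: dict = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)


def read_genotypes(path, dialect: str = "genalex-simplified") -> GenotypeMatrix:
    """Parse a genotype table in one of the supported dialects."""
    if dialect == "genalex-simplified":
        return _read_genalex(path)
    if dialect == "dosage-csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genalex(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 4:
        raise ValueError(f"{path}: too short for a Genalex-style file")
    header = lines[2].split(",")
    if len(header) < 4 or header[0].strip().lower() != "sample":
        raise ValueError(f"{path}: line 3: expected 'Sample,Pop,<locus columns>'")
    locus_ids = [h.strip() for h in header[2::2]]
    n_loci = len(locus_ids)
    samples, pops, rows = [], [], []
    for lineno, ln in enumerate(lines[3:], start=4):
        if not ln.strip():
            continue
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 2 + 2 * n_loci:
            raise ValueError(
                f"{path}: line {lineno}: expected {2 + 2 * n_loci} fields, "
                f"got {len(parts)} (ragged row)"
            )
        samples.append(parts[0])
        pops.append(parts[1])
        alleles = []
        for tok in parts[2:]:
            if tok not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: line {lineno}: allele code {tok!r} is not "
                    "biallelic (expected 0=missing, 1, 2)"
                )
            alleles.append(int(tok))
        a = np.array(alleles, dtype=float).reshape(n_loci, 2)
        dos = (a == 2).sum(axis=1).astype(float)
        dos[(a == 0).any(axis=1)] = np.nan
        rows.append(dos)
    return GenotypeMatrix(
        dosages=np.array(rows),
        populations=np.array(pops),
        locus_ids=locus_ids,
        sample_ids=samples,
    )


def _read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "pop" not in cols:
        raise ValueError(f"{path}: dosage CSV needs 'sample' and 'pop' columns")
    loci = [c for c in df.columns if c not in (cols["sample"], cols["pop"])]
    dos = df[loci].to_numpy(dtype=float)
    bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: line {r + 2}: dosage {dos[r, c]!r} at locus {loci[c]!r} "
            "is not in {0, 1, 2, NA}"
        )
    return GenotypeMatrix(
        dosages=dos,
        populations=df[cols["pop"]].to_numpy(),
        locus_ids=loci,
        sample_ids=df[cols["sample"]].astype(str).tolist(),
    )


def write_genalex(g: GenotypeMatrix, path, title: str = "synthetic genotypes") -> None:
    """Write the simplified Genalex CSV dialect (see module docstring)."""
    pop_ids = g.pop_ids
    sizes = [int((g.populations == p).sum()) for p in pop_ids]
    n_ind, n_loci = g.dosages.shape
    with open(path, "w") as fh:
        fh.write(",".join(str(v) for v in [n_loci, n_ind, len(pop_ids)] + sizes) + "\n")
        fh.write(f"{title}\n")
        cols = ["Sample", "Pop"]
        for loc in g.locus_ids:
            cols += [loc, ""]
        fh.write(",".join(cols) + "\n")
        for i in range(n_ind):
            row = [str(g.sample_ids[i]), str(g.populations[i])]
            for d in g.dosages[i]:
                if np.isnan(d):
                    row += ["0", "0"]
                else:
                    n_alt = int(d)
                    row += ["2"] * n_alt + ["1"] * (2 - n_alt)
            fh.write(",".join(row) + "\n")


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components a, b, c for two samples.

    ``n`` are genotyped-individual counts, ``p`` alternate-allele
    frequencies, ``h`` observed heterozygote frequencies, vectorized over
    loci.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(g: GenotypeMatrix) -> tuple[pd.DataFrame, dict]:
    """Pairwise Weir–Cockerham theta between all population pairs.

    Multilocus combination is a ratio of sums across loci. Per pair, loci
    with fewer than 2 genotyped individuals in either population are
    skipped; a pair with no usable locus raises; a pair monomorphic at
    every usable locus scores 0 with a warning. Returns the symmetric Fst
    matrix (zero diagonal) and metadata (loci used per pair, count of
    negative estimates).
    """
    pop_ids = g.pop_ids
    if len(pop_ids) < 2:
        raise ValueError("need at least 2 populations")
    stats = {}
    for p in pop_ids:
        sel = g.dosages[g.populations == p]
        if sel.shape[0] < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
        n = np.sum(~np.isnan(sel), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.nansum(sel, axis=0) / (2.0 * n)
            het = np.sum(sel == 1.0, axis=0) / n  # missing never equals 1
        stats[p] = (n, freq, het)

    k = len(pop_ids)
    fst = np.zeros((k, k))
    loci_used: dict[str, int] = {}
    negatives = 0
    for i in range(k):
        for j in range(i + 1, k):
            n1, p1, h1 = stats[pop_ids[i]]
            n2, p2, h2 = stats[pop_ids[j]]
            usable = (n1 >= 2) & (n2 >= 2)
            if not usable.any():
                raise ValueError(
                    f"pair ({pop_ids[i]!r}, {pop_ids[j]!r}) has no locus with "
                    ">= 2 genotyped individuals in both populations"
                )
            a, b, c = _wc_components(
                n1[usable], p1[usable], h1[usable],
                n2[usable], p2[usable], h2[usable],
            )
            num = float(a.sum())
            den = float((a + b + c).sum())
            if den == 0.0:
                warnings.warn(
                    f"pair ({pop_ids[i]!r}, {pop_ids[j]!r}) is monomorphic at "
                    "every usable locus; Fst set to 0",
                    stacklevel=2,
                )
                theta = 0.0
            else:
                theta = num / den
            if theta < 0:
                negatives += 1
            fst[i, j] = fst[j, i] = theta
            loci_used[f"{pop_ids[i]}|{pop_ids[j]}"] = int(usable.sum())
    df = pd.DataFrame(fst, index=pop_ids, columns=pop_ids)
    meta = {"loci_used": loci_used, "n_negative": negatives}
    return df, meta
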