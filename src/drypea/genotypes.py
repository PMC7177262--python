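"""Genotype matrix container and file formats.

Calls are coded as the count of the alternate allele per line and marker:
0 and 2 are the two homozygotes, 1 a (rare, in inbred material) residual
heterozygote, and ``NaN`` a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_vcf", "read_table"]

#: VCF position units per centimorgan on the pseudo-contigs written by
#: :meth:`GenotypeMatrix.to_vcf` (positions are cM x 1e5, rounded).
_BP_PER_CM = 100_000


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic call matrix with population labels.

    Parameters
    ----------
    calls:
        DataFrame indexed by line id with one column per marker; values in
        {0, 1, 2} or NaN for missing.
    populations:
        Population label per line (index-aligned with ``calls``).
    positions:
        Optional marker map with columns ``chrom`` and ``cm``, indexed by
        marker id.
    """

    calls: pd.DataFrame
    populations: pd.Series | None = None
    positions: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(float)
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate marker ids")
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate line ids")
        if self.populations is None:
            self.populations = pd.Series("pop1", index=self.calls.index)
        else:
            self.populations = self.populations.reindex(self.calls.index)
            if self.populations.isna().any():
                missing = self.populations.index[self.populations.isna()]
                raise ValueError(f"lines without population label: {list(missing)[:5]}")
        if self.positions is not None:
            self.positions = self.positions.reindex(self.calls.columns)
        vals = self.calls.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing")

    # ------------------------------------------------------------------
    @property
    def line_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missing_rate(self) -> pd.Series:
        """Per-marker fraction of missing calls."""
        return self.calls.isna().mean(axis=0)

    def allele_freq(self) -> pd.Series:
        """Alternate-allele frequency per marker over non-missing calls.

        A heterozygote contributes one copy of each allele.
        """
        return self.calls.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker (allele-based)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        calls = self.calls
        if lines is not None:
            calls = calls.loc[list(lines)]
        if markers is not None:
            calls = calls.loc[:, list(markers)]
        pos = None
        if self.positions is not None:
            pos = self.positions.loc[calls.columns]
        return GenotypeMatrix(calls.copy(), self.populations.loc[calls.index].copy(), pos)

    def copy(self) -> "GenotypeMatrix":
        pos = None if self.positions is None else self.positions.copy()
        return GenotypeMatrix(self.calls.copy(), self.populations.copy(), pos)

    # -------------------------------- I/O ------------------------------
    def to_table(self, path: str | Path) -> None:
        """Write a tab-separated lines x markers table (first columns:
        ``line``, ``population``; missing as ``NA``)."""
        out = self.calls.copy()
        out.insert(0, "population", self.populations)
        out.index.name = "line"
        out.to_csv(path, sep="\t", na_rep="NA")

    def to_vcf(self, path: str | Path) -> None:
        """Write an uncompressed VCF (GT field only, ``./.`` for missing).

        Each chromosome becomes one pseudo-contig; positions are map
        positions in cM scaled by 1e5 and rounded. Markers without map
        positions go on a single contig ``chrUn`` at consecutive positions.
        """
        lines = list(self.calls.index)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=drypea\n")
            if self.positions is not None:
                for chrom in pd.unique(self.positions["chrom"].dropna()):
                    fh.write(f"##contig=<ID={chrom}>\n")
            else:
                fh.write("##contig=<ID=chrUn>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(lines)
                + "\n"
            )
            gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, marker in enumerate(self.calls.columns):
                if self.positions is not None:
                    chrom = str(self.positions.loc[marker, "chrom"])
                    pos = int(round(float(self.positions.loc[marker, "cm"]) * _BP_PER_CM))
                    pos = max(pos, 1)
                else:
                    chrom, pos = "chrUn", j + 1
                col = self.calls[marker].to_numpy()
                gts = "\t".join(
                    "./." if np.isnan(v) else gt_codes[v] for v in col
                )
                fh.write(f"{chrom}\t{pos}\t{marker}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_table(path: str | Path, populations: pd.Series | None = None) -> GenotypeMatrix:
    """Read the tab-separated table written by :meth:`GenotypeMatrix.to_table`."""
    df = pd.read_csv(path, sep="\t", index_col="line", na_values=["NA"])
    pops = None
    if "population" in df.columns:
        pops = df.pop("population")
    if populations is not None:
        pops = populations
    return GenotypeMatrix(df, pops)


def read_vcf(path: str | Path, populations: pd.Series | None = None) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Only the GT field is used; the alternate-allele count per line is the
    call. Map positions are recovered as position / 1e5 cM.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, cms, rows = [], [], [], []
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        ids.append(vid)
        chroms.append(var.CHROM)
        cms.append(var.POS / _BP_PER_CM)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        row = np.where(gt == 3, 2.0, gt)
        row[gt == 2] = np.nan
        rows.append(row)
    calls = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    positions = pd.DataFrame({"chrom": chroms, "cm": cms}, index=ids)
    return GenotypeMatrix(calls, populations, positions)
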