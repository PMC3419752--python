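"""Internal allele registry and count kernels.

Most statistics in this package reduce genotype tables to per-locus allele
counts, heterozygote-carrier counts and non-missing sample sizes.  To keep
permutation/bootstrap/drift loops fast these are computed with a single
flattened ``bincount`` per sample: allele codes are first mapped to dense
per-locus indices by a :class:`LocusRegistry`, then offset so that every
(locus, allele) class occupies one slot of a shared 1-D axis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .genepop import MISSING, GenotypeTable


class LocusRegistry:
    """Dense allele indexing over a fixed locus list.

    Built from one or more genotype tables so that every allele seen anywhere
    in a study has a stable index; statistics computed on subsets then share
    the same allele classes (needed e.g. for assignment smoothing priors).
    """

    def __init__(self, locus_names: Sequence[str], alleles_per_locus: list[np.ndarray]):
        self.locus_names = list(locus_names)
        self.alleles = [np.asarray(a, dtype=np.int32) for a in alleles_per_locus]
        self.k = np.array([len(a) for a in self.alleles], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.k)])
        self.total = int(self.offsets[-1])
        # segment id per flattened slot
        self.segment = np.repeat(np.arange(len(self.alleles)), self.k)

    @classmethod
    def from_tables(cls, tables: Sequence[GenotypeTable]) -> "LocusRegistry":
        loci = tables[0].locus_names
        for t in tables[1:]:
            if t.locus_names != loci:
                raise ValueError("tables disagree on locus lists")
        per_locus = []
        for j in range(len(loci)):
            codes = np.concatenate([t.calls[:, j, :].ravel() for t in tables])
            codes = np.unique(codes[codes != MISSING])
            per_locus.append(codes)
        return cls(loci, per_locus)

    def encode(self, calls: np.ndarray) -> np.ndarray:
        """Map an ``(n, L, 2)`` code array to flattened slot indices.

        Returns an ``(n, L, 2)`` int64 array of global slot indices
        (offset + within-locus index), with -1 for missing calls.
        """
        n, L, _ = calls.shape
        if L != len(self.alleles):
            raise ValueError("locus count mismatch")
        out = np.full(calls.shape, -1, dtype=np.int64)
        for j, alleles in enumerate(self.alleles):
            col = calls[:, j, :]
            ok = col != MISSING
            pos = np.searchsorted(alleles, col[ok])
            if pos.size and (
                (pos >= len(alleles)).any() or (alleles[pos] != col[ok]).any()
            ):
                raise ValueError(
                    f"allele code absent from registry at locus "
                    f"{self.locus_names[j]!r}"
                )
            out[:, j, :][ok] = pos + self.offsets[j]
        return out

    def counts(
        self, enc: np.ndarray, rows: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-locus sample sizes and flattened allele / het-carrier counts.

        Parameters
        ----------
        enc
            Encoded calls from :meth:`encode`.
        rows
            Optional individual subset (integer index array).

        Returns
        -------
        n_ind : (L,) individuals with a non-missing call per locus
        allele : (total,) gene-copy count per (locus, allele) slot
        het : (total,) count of heterozygous individuals carrying each allele
        """
        sub = enc if rows is None else enc[rows]
        a, b = sub[:, :, 0], sub[:, :, 1]
        ok = a >= 0
        flat = sub[ok.nonzero()[0], ok.nonzero()[1], :].ravel()
        allele = np.bincount(flat, minlength=self.total)
        hmask = ok & (a != b)
        hflat = sub[hmask.nonzero()[0], hmask.nonzero()[1], :].ravel()
        het = np.bincount(hflat, minlength=self.total)
        n_ind = ok.sum(axis=0)
        return n_ind, allele, het

    def frequencies(self, enc: np.ndarray) -> list[np.ndarray]:
        """Observed per-locus allele frequency vectors (NaN-free; loci with
        no data get a uniform placeholder flagged by zero n)."""
        n_ind, allele, _ = self.counts(enc)
        out = []
        for j in range(len(self.alleles)):
            seg = allele[self.offsets[j] : self.offsets[j + 1]].astype(float)
            tot = seg.sum()
            out.append(seg / tot if tot > 0 else np.full(len(seg), np.nan))
        return out
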