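"""F1-hybrid additive and dominance design matrices from parental genotypes.

For a cross between two inbred parents with marker codes in {-1, +1}, the
hybrid's additive state is the parental mean (so +1, -1 or 0) and its
dominance state is 1 exactly where the parents carry opposite homozygous
codes (the hybrid is heterozygous) and 0 otherwise.  Stacking these states
over hybrids gives the design matrices K_A (n x m, codes -1/0/+1) and
K_D (n x m, codes 0/1) that carry the additive and dominance marker effects
in the prediction models.

Residually heterozygous parents (code 0) are handled by policy: the default
"expected" policy uses the expected gamete contribution, giving fractional
K_A entries (+-0.5) and expected heterozygosity in K_D (0.5); the "strict"
policy rejects them, matching the inbred-parent assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix


@dataclass
class MatingDesign:
    """Crossing table: one record per hybrid (hybrid, female, male, group)."""

    table: pd.DataFrame

    REQUIRED = ("hybrid", "female", "male", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"mating design missing columns: {missing}")
        if self.table["hybrid"].duplicated().any():
            dup = self.table.loc[self.table["hybrid"].duplicated(), "hybrid"]
            raise ValueError(f"duplicate hybrid IDs: {sorted(set(dup))[:5]}")
        self.table = self.table.reset_index(drop=True)

    @property
    def hybrids(self) -> list[str]:
        return self.table["hybrid"].tolist()

    @property
    def n_hybrids(self) -> int:
        return len(self.table)

    def parents(self) -> set[str]:
        return set(self.table["female"]) | set(self.table["male"])


@dataclass
class HybridDesign:
    """Per-hybrid additive (K_A) and dominance (K_D) design matrices."""

    hybrids: list[str]
    markers: list[str]
    k_a: np.ndarray
    k_d: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.hybrids), len(self.markers))
        if self.k_a.shape != shape or self.k_d.shape != shape:
            raise ValueError("K_A / K_D shape mismatch with hybrid/marker IDs")

    def k_a_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.k_a, index=self.hybrids, columns=self.markers)

    def k_d_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.k_d, index=self.hybrids, columns=self.markers)


def make_hybrid_design(
    genotypes: GenotypeMatrix,
    design: MatingDesign,
    het_policy: str = "expected",
) -> HybridDesign:
    """Build K_A and K_D for every cross in ``design``.

    ``K_A[h] = (female + male) / 2`` and ``K_D[h] = |female - male| / 2``
    per marker; for inbred parents this yields exactly the -1/0/+1 and 0/1
    codings.  Rows follow the design record order; columns follow the
    genotype matrix so effect vectors stay aligned across modules.

    Parameters
    ----------
    het_policy
        "expected" allows heterozygous parental calls (fractional entries);
        "strict" raises if any parent used in a cross carries a 0 code.
    """
    if het_policy not in ("expected", "strict"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if genotypes.has_missing():
        raise ValueError(
            "genotype matrix has missing calls; run impute_naive first"
        )
    row_of = {line: i for i, line in enumerate(genotypes.lines)}
    unknown = sorted(design.parents() - set(row_of))
    if unknown:
        raise KeyError(f"parent line(s) not in genotype matrix: {unknown[:5]}")

    fem = design.table["female"].map(row_of).to_numpy()
    mal = design.table["male"].map(row_of).to_numpy()
    if het_policy == "strict":
        used = np.unique(np.concatenate([fem, mal]))
        het_lines = [
            genotypes.lines[i]
            for i in used
            if (genotypes.codes[i] == 0).any()
        ]
        if het_lines:
            raise ValueError(
                "heterozygous parental calls under strict policy in "
                f"line(s): {het_lines[:5]}"
            )
    f_codes = genotypes.codes[fem]
    m_codes = genotypes.codes[mal]
    k_a = (f_codes + m_codes) / 2.0
    k_d = np.abs(f_codes - m_codes) / 2.0
    return HybridDesign(
        hybrids=design.hybrids,
        markers=list(genotypes.markers),
        k_a=k_a,
        k_d=k_d,
    )


def design_summary(hd: HybridDesign) -> dict[str, pd.Series]:
    """Per-hybrid heterozygosity (mean K_D) and per-marker segregation counts.

    Segregation counts tally, per marker, how many hybrids are heterozygous
    (K_D > 0) — i.e. at how many crosses the marker separates the parents.
    """
    het = pd.Series(hd.k_d.mean(axis=1), index=hd.hybrids, name="heterozygosity")
    seg = pd.Series(
        (hd.k_d > 0).sum(axis=0), index=hd.markers, name="n_segregating"
    )
    return {"hybrid_heterozygosity": het, "marker_segregation": seg}
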