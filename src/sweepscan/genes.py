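"""Gene-level polymorphism profiling.

For a candidate gene this produces: the variant sites inside the gene plus
flanks, the per-sample genotype-class matrix behind "haplotype heatmap"
figures (REF for 0/0, ALT-carrying for 0/1 or 1/1 — no phasing is done, the
classes are a pure function of dosage), per-group per-bp nucleotide
diversity over the interval, and "characteristic" loci whose ALT-carrier
frequency separates two groups by at least a margin, with runs of adjacent
characteristic sites annotated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GeneModel, GenotypeMatrix
from .sweep import window_pi

logger = logging.getLogger(__name__)

REF_CLASS = "REF"
ALT_CLASS = "ALT"
MISSING_CLASS = "NA"

_CLASS_OF_DOSAGE = {0: REF_CLASS, 1: ALT_CLASS, 2: ALT_CLASS, MISSING: MISSING_CLASS}


def genotype_class(dosage: int) -> str:
    """Map a dosage to its heatmap class (0 -> REF; 1, 2 -> ALT-carrying)."""
    try:
        return _CLASS_OF_DOSAGE[int(dosage)]
    except KeyError:
        raise ValueError(f"invalid dosage {dosage}") from None


@dataclass
class GeneProfile:
    gene: GeneModel
    flank: int
    variant_sites: pd.DataFrame  # chrom, pos, ref, alt, id
    genotype_class: pd.DataFrame  # samples x sites, REF/ALT/NA strings
    pi_by_group: dict[str, float]
    characteristic_loci: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pos", "carrier_freq_group1", "carrier_freq_group2",
                     "difference", "run_id"]
        )
    )

    @property
    def n_sites(self) -> int:
        return len(self.variant_sites)


def gene_profile(
    gm: GenotypeMatrix,
    gene: GeneModel,
    flank: int = 50_000,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> GeneProfile:
    """Profile one gene's polymorphism over [start - flank, end + flank].

    ``groups`` maps group name -> sample ids; per-group pi is computed over
    the flanked interval with the same per-bp estimator the sweep scan uses.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start, end = gene.interval(flank)
    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    in_iv = (chrom_arr == gene.chrom) & (pos_arr >= start) & (pos_arr <= end)
    sites = gm.variants.loc[in_iv].reset_index(drop=True)
    if sites.empty:
        warnings.warn(
            f"no variants within {gene.gene_name} +/- {flank} bp", stacklevel=2
        )
    dosage = gm.dosage[:, np.flatnonzero(in_iv)]
    classes = pd.DataFrame(
        np.vectorize(genotype_class)(dosage) if dosage.size else
        np.empty((gm.n_samples, 0), dtype=object),
        index=gm.samples,
        columns=[f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])],
    )
    pi_by_group: dict[str, float] = {}
    for name, members in (groups or {}).items():
        pi_by_group[name] = window_pi(gm, list(members), (gene.chrom, start, end))
    return GeneProfile(
        gene=gene,
        flank=flank,
        variant_sites=sites,
        genotype_class=classes,
        pi_by_group=pi_by_group,
    )


def carrier_frequency(
    profile: GeneProfile, samples: Sequence[str]
) -> np.ndarray:
    """Fraction of non-missing samples in class ALT-carrying, per site."""
    sub = profile.genotype_class.loc[list(samples)]
    alt = (sub == ALT_CLASS).sum(axis=0).to_numpy(dtype=float)
    obs = (sub != MISSING_CLASS).sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(obs > 0, alt / obs, np.nan)


def characteristic_loci(
    profile: GeneProfile,
    group1: Sequence[str],
    group2: Sequence[str],
    margin: float = 0.5,
) -> pd.DataFrame:
    """Sites whose ALT-carrier frequency differs between groups by >= margin.

    Returns a position-sorted table with both carrier frequencies, the
    signed difference (group1 - group2), and a ``run_id`` labelling runs of
    *adjacent* reported sites (consecutive in the profile's site list).
    """
    if profile.n_sites == 0:
        return profile.characteristic_loci.copy()
    f1 = carrier_frequency(profile, group1)
    f2 = carrier_frequency(profile, group2)
    diff = f1 - f2
    with np.errstate(invalid="ignore"):
        hit = np.abs(diff) >= margin
    hit &= np.isfinite(diff)
    idx = np.flatnonzero(hit)
    run_ids = np.zeros(len(idx), dtype=int)
    run = 0
    for k in range(1, len(idx)):
        if idx[k] != idx[k - 1] + 1:
            run += 1
        run_ids[k] = run
    out = pd.DataFrame(
        {
            "pos": profile.variant_sites["pos"].to_numpy()[idx],
            "carrier_freq_group1": f1[idx],
            "carrier_freq_group2": f2[idx],
            "difference": diff[idx],
            "run_id": run_ids,
        }
    )
    return out.sort_values("pos", kind="stable").reset_index(drop=True)


def plot_genotype_heatmap(profile: GeneProfile, path, group_of=None) -> None:
    """Render the REF/ALT genotype-class matrix as a two-color heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code = profile.genotype_class.replace(
        {REF_CLASS: 0, ALT_CLASS: 1, MISSING_CLASS: np.nan}
    ).to_numpy(dtype=float)
    if group_of:
        order = sorted(
            range(len(profile.genotype_class.index)),
            key=lambda i: group_of.get(profile.genotype_class.index[i], ""),
        )
        code = code[order]
    fig, ax = plt.subplots(figsize=(10, 6))
    cmap = ListedColormap(["#f6a8c0", "#5b8fd6"])  # pink REF, blue ALT
    ax.imshow(code, aspect="auto", interpolation="nearest", cmap=cmap,
              vmin=0, vmax=1)
    ax.set_xlabel(f"{profile.gene.gene_name} SNP sites (n={profile.n_sites})")
    ax.set_ylabel("individuals")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
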