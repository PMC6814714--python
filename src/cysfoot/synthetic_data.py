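"""Synthetic PSM tables and toy structures with known ground truth.

The generator emulates the statistical structure of a spectral-counting
cysteine-footprinting experiment on a single purified protein:

* a toy protein with cysteines at chosen positions (by default the 12
  cysteine sites of murine αE-catenin: C116, C228, C324, C337, C438, C461,
  C526, C720, C767, C772, C787, C793), built so that every cysteine falls
  in a detectable tryptic peptide;
* per site, per replicate, a spectral depth drawn Poisson(mean_depth) — MS
  sampling depth varies between runs — and a modified count drawn
  Binomial(depth, p_site), where p_site is the ground-truth labeling
  probability for the condition;
* each count emitted as one PSM of the shortest tryptic peptide containing
  the site (leftmost on ties); modifications on multi-cysteine peptides
  are flagged unlocalized at a configurable failure rate;
* optional replicate heterogeneity as a logit-normal perturbation of
  p_site (off by default) to exercise the weighted-standard-error path.

Everything is driven by a single integer seed; identical seeds give
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .psm_io import PSMRecord, PSMTable
from .sequence_io import (
    DigestParams,
    PeptideMatch,
    ProteinRecord,
    cys_sites_in_peptide,
    tryptic_digest,
)

__all__ = [
    "ALPHA_E_CATENIN_CYS_SITES",
    "SimulationDesign",
    "make_toy_protein",
    "simulate_psm_table",
    "write_truth_table",
    "make_sphere_fixture",
]

#: The 12 native cysteine positions of murine αE-catenin (1-based).
ALPHA_E_CATENIN_CYS_SITES: tuple[int, ...] = (
    116, 228, 324, 337, 438, 461, 526, 720, 767, 772, 787, 793,
)

_DEFAULT_LENGTH = 906  # full-length murine αE-catenin

# Residues used for random sequence fill: no C (placed explicitly), no K/R
# (placed explicitly to control digestion), no P (would suppress cleavage).
_FILL_ALPHABET = "ADEFGHILMNQSTVWY"


def make_toy_protein(
    length: int = _DEFAULT_LENGTH,
    cys_positions: Sequence[int] = ALPHA_E_CATENIN_CYS_SITES,
    seed: int = 0,
    *,
    protein_id: str = "toy_catenin",
    cleavage_spacing: int = 12,
    digest_params: DigestParams | None = None,
) -> ProteinRecord:
    """Random protein with cysteines at fixed positions, digestible by design.

    K/R residues are interleaved roughly every ``cleavage_spacing`` positions
    (never on a requested cysteine position) so that under tryptic digestion
    every cysteine lies in at least one peptide within the default length
    window. The construction is verified against the digest and raises if
    any cysteine is unplaceable.
    """
    cys = sorted(set(int(p) for p in cys_positions))
    if cys and (cys[0] < 1 or cys[-1] > length):
        raise ValueError("cysteine positions outside sequence length")
    if len(cys) != len(set(cys_positions)):
        raise ValueError("duplicate cysteine positions")
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(_FILL_ALPHABET), size=length))
    cys_set = set(cys)
    for pos in range(cleavage_spacing, length, cleavage_spacing):
        # pos is 1-based residue index for a cleavage residue
        if pos in cys_set or (pos + 1) in cys_set:
            continue
        residues[pos - 1] = rng.choice(["K", "R"])
    for p in cys:
        residues[p - 1] = "C"
    protein = ProteinRecord(id=protein_id, sequence="".join(residues))

    params = digest_params or DigestParams()
    covered = set()
    for match in tryptic_digest(protein, params):
        covered.update(cys_sites_in_peptide(match, protein))
    missing = cys_set - covered
    if missing:
        raise ValueError(
            f"could not place cysteines in detectable peptides: {sorted(missing)}"
        )
    return protein


@dataclass
class SimulationDesign:
    """Ground-truth design of a synthetic footprinting experiment.

    ``site_probs`` maps condition label → {residue index → labeling
    probability}. Defaults mirror the study layout: 5 replicates per
    condition and a mean spectral depth of 50 PSMs per site per replicate.
    """

    protein: ProteinRecord = field(default_factory=make_toy_protein)
    site_probs: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    replicates: int = 5
    mean_depth: float = 50.0
    localization_failure_rate: float = 0.2
    replicate_sd_logit: float = 0.0  # logit-scale replicate heterogeneity
    seed: int = 0
    digest_params: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.localization_failure_rate <= 1):
            raise ValueError("localization_failure_rate must be in [0,1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.site_probs:
            self.site_probs = {
                "ctrl": {p: 0.3 for p in self.protein.cys_positions}
            }
        for cond, probs in self.site_probs.items():
            for site, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"p={p} for site {site} in {cond!r}")
                if site not in self.protein.cys_positions:
                    raise ValueError(
                        f"site {site} in condition {cond!r} is not a "
                        "cysteine of the design protein"
                    )


def _site_peptide_index(
    protein: ProteinRecord, params: DigestParams
) -> dict[int, PeptideMatch]:
    """Shortest digest peptide containing each cysteine (leftmost on ties)."""
    best: dict[int, PeptideMatch] = {}
    for match in tryptic_digest(protein, params):
        for site in cys_sites_in_peptide(match, protein):
            cur = best.get(site)
            cand_key = (match.end - match.start, match.start)
            if cur is None or cand_key < (cur.end - cur.start, cur.start):
                best[site] = match
    return best


def simulate_psm_table(design: SimulationDesign) -> PSMTable:
    """Draw a PSM table from the design's generative model.

    Sites are grouped by their assigned (shortest covering) tryptic
    peptide. For each (condition, replicate, peptide): a spectral depth
    n ~ Poisson(mean_depth) is drawn, and in each of the n PSMs every
    cysteine of the peptide is independently modified with its own
    p_site — so per site the modified count is Binomial(n, p_site), while
    PSMs of a shared peptide stay jointly consistent with spectral-count
    tallying. Modified PSMs of multi-cysteine peptides are flagged
    unlocalized with probability ``localization_failure_rate``.
    """
    rng = np.random.default_rng(design.seed)
    protein = design.protein
    pep_for_site = _site_peptide_index(protein, design.digest_params)
    records: list[PSMRecord] = []
    for cond in sorted(design.site_probs):
        probs = design.site_probs[cond]
        # sites sharing a covering peptide are simulated jointly
        by_peptide: dict[PeptideMatch, list[int]] = {}
        for site in sorted(probs):
            match = pep_for_site.get(site)
            if match is None:
                raise ValueError(f"no digest peptide covers site {site}")
            by_peptide.setdefault(match, []).append(site)
        for rep in range(1, design.replicates + 1):
            for match in sorted(by_peptide, key=lambda m: m.start):
                sites = by_peptide[match]
                p_rep = []
                for site in sites:
                    p = probs[site]
                    if design.replicate_sd_logit > 0 and 0 < p < 1:
                        logit = math.log(p / (1 - p)) + rng.normal(
                            0.0, design.replicate_sd_logit
                        )
                        p = 1.0 / (1.0 + math.exp(-logit))
                    p_rep.append(p)
                n = int(rng.poisson(design.mean_depth))
                if n == 0:
                    continue
                n_cys = len(cys_sites_in_peptide(match, protein))
                modified = rng.random((n, len(sites))) < np.asarray(p_rep)
                unloc_draw = rng.random(n) < design.localization_failure_rate
                for j in range(n):
                    offsets = tuple(
                        site - match.start + 1
                        for site, m in zip(sites, modified[j])
                        if m
                    )
                    unlocalized = bool(offsets) and n_cys > 1 and unloc_draw[j]
                    records.append(
                        PSMRecord(
                            condition=cond,
                            replicate=str(rep),
                            protein_id=protein.id,
                            peptide=match.peptide,
                            mod_offsets=offsets,
                            localized=not unlocalized,
                        )
                    )
    return PSMTable(
        records=records,
        provenance=f"simulated (seed={design.seed})",
    )


def write_truth_table(design: SimulationDesign, path: str | Path) -> None:
    """Write the ground-truth per-site labeling probabilities as TSV."""
    rows = [
        {"condition": cond, "residue": site, "p_site": p}
        for cond in sorted(design.site_probs)
        for site, p in sorted(design.site_probs[cond].items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def make_sphere_fixture(
    geometry_spec: str = "isolated",
    *,
    distance: float = 10.0,
    n_cage: int = 60,
    cage_radius: float = 3.0,
    element: str = "S",
    seed: int = 0,
):
    """Synthetic atom arrangements for exercising the SASA engine.

    ``geometry_spec`` ∈ {"isolated", "pair", "cage"}: a single atom at the
    origin; two atoms ``distance`` Å apart on the x axis; or a central atom
    enclosed by a dense shell of ``n_cage`` atoms at ``cage_radius`` Å
    (fully burying the center for standard radii).
    """
    from .structure_sasa import VDW_RADII, StructureModel, _assign_radii

    if geometry_spec == "isolated":
        coords = np.zeros((1, 3))
    elif geometry_spec == "pair":
        coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    elif geometry_spec == "cage":
        from .structure_sasa import sphere_points

        shell = cage_radius * sphere_points(n_cage)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
    else:
        raise ValueError(f"unknown geometry_spec {geometry_spec!r}")
    n = len(coords)
    elements = np.array([element] * n)
    return StructureModel(
        names=np.array([element] * n),
        residue_names=np.array(["UNK"] * n),
        chains=np.array(["A"] * n),
        residue_numbers=np.arange(1, n + 1),
        elements=elements,
        radii=_assign_radii(elements),
        coords=coords[None, :, :],
    )
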