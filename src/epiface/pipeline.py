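"""Per-complex orchestration and cross-complex aggregation.

``run_complex`` executes the full analysis in dependency order: burial and
interface sets, sub-epitope decomposition, exposedness, patches and
stretches, hydrophobic clusters, polar and ring interactions, polar-atom
roles and the charge profile.  Partial inputs degrade gracefully (a
structure without waters yields no water-mediated count, flagged rather
than reported as zero).  ``aggregate`` pools per-complex reports into
mean +/- sd descriptors and pooled amino-acid compositions.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .charges import ChargeProfile, charge_profile
from .hydrophobic import (
    ClusterStats,
    HydrophobicClusterSet,
    HydrophobicParams,
    cluster_stats,
    find_hydrophobic_clusters,
)
from .polar import (
    InteractionTable,
    PolarParams,
    WaterBridgeSummary,
    detect_hbonds,
    detect_salt_bridges,
    detect_water_mediated,
    polar_roles,
)
from .rings import (
    ResidueRoleProfile,
    RingParams,
    detect_pi_ion,
    detect_pi_pi,
    residue_role_profiles,
    rings_of,
)
from .sasa import (
    ExposednessProfile,
    InterfaceSets,
    SubEpitopeDecomposition,
    decompose_epitope,
    epitope_paratope,
    exposedness_profile,
)
from .structures import (
    CDR_LABELS,
    ComplexStructure,
    DEFAULT_SCHEME,
    RegionScheme,
    ResidueKey,
    assign_region,
    classify_chemistry,
    read_complex,
)
from .topology import (
    PatchSet,
    SsComposition,
    StretchDecomposition,
    epitope_patches,
    linear_stretches,
    ss_composition,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    """Every knob of the per-complex analysis, with study defaults."""

    probe: float = 1.4
    n_points: int = 960
    exposedness_n_points: int = 4000
    calibration: float = 1.0
    keep_waters: bool = True
    scheme: RegionScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    hydrophobic: HydrophobicParams = field(default_factory=HydrophobicParams)
    polar: PolarParams = field(default_factory=PolarParams)
    rings: RingParams = field(default_factory=RingParams)
    pH: float = 7.2
    gap_tolerance: int = 1
    prune_dist: float = 4.0
    min_patch_fraction: float = 0.05
    min_ag_residues: int | None = None
    max_resolution: float | None = None
    pka_table: dict | None = None
    dssp_file: str | None = None


class ComplexSkipped(RuntimeError):
    """The complex failed a pipeline-level filter."""


@dataclass
class ComplexReport:
    """All descriptors of one antibody-antigen complex."""

    name: str
    a_interface: float
    epitope: set[ResidueKey]
    paratope: set[ResidueKey]
    sets: InterfaceSets
    decomposition: SubEpitopeDecomposition
    exposedness: ExposednessProfile
    patches: PatchSet
    stretches: StretchDecomposition
    ss: SsComposition | None
    clusters: HydrophobicClusterSet
    cluster_summary: ClusterStats
    interactions: InteractionTable
    water_summary: WaterBridgeSummary
    polar_role_distribution: dict
    role_profiles: ResidueRoleProfile
    charge: ChargeProfile
    flags: list[str] = field(default_factory=list)

    # -- derived scalar descriptors ----------------------------------------

    @property
    def paratope_size(self) -> int:
        return len(self.paratope)

    @property
    def epitope_size(self) -> int:
        return len(self.epitope)

    @property
    def heavy_fraction(self) -> float:
        n = len(self.paratope)
        if n == 0:
            return 0.0
        return sum(1 for r in self.paratope if r.role == "heavy") / n

    def cdr_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in CDR_LABELS + ("FwH", "FwL")}
        for r in self.paratope:
            counts[assign_region(r, DEFAULT_SCHEME)] += 1
        return counts

    def interaction_counts(self) -> dict[str, int]:
        return self.interactions.counts()

    def aa_composition(self, residues) -> dict[str, float]:
        counts = Counter(r.aa3 for r in residues)
        n = sum(counts.values())
        return {aa: c / n for aa, c in counts.items()} if n else {}

    def scalars(self) -> dict[str, float]:
        """The per-complex scalar descriptors entering aggregation."""
        return {
            "a_interface": self.a_interface,
            "paratope_size": self.paratope_size,
            "epitope_size": self.epitope_size,
            "heavy_fraction": self.heavy_fraction,
            "n_patches": self.patches.n_patches,
            "largest_patch_fraction": self.patches.largest_fraction,
            "n_stretches": len(self.stretches.stretches),
            "longest_stretch": self.stretches.longest,
            "n_hydrophobic_clusters": self.cluster_summary.n_clusters,
            "biggest_cluster_atoms": self.cluster_summary.n_atoms,
            "biggest_cluster_residues": self.cluster_summary.n_residues,
            "net_charge_paratope": self.charge.net_charge_paratope,
            "net_charge_epitope": self.charge.net_charge_epitope,
        }

    def to_residue_table(self) -> pd.DataFrame:
        """Per-residue interface annotation of the antigen.

        One row per antigen residue: identity, membership in the epitope
        and each sub-epitope subset, exposedness class and buried area.
        """
        exposed_class = {}
        for res in self.exposedness.deep:
            exposed_class[res] = "deep"
        for res in self.exposedness.medium:
            exposed_class[res] = "medium"
        for res in self.exposedness.superficial:
            exposed_class[res] = "superficial"
        buried_by_res: dict = {}
        for atom, area in self.sets.buried_area.items():
            buried_by_res[atom.residue] = buried_by_res.get(atom.residue, 0.0) + area

        dec = self.decomposition
        rows = []
        seen = set()
        for atom in self.sets.ag_sasa.atoms:
            res = atom.residue
            if res in seen:
                continue
            seen.add(res)
            row = {
                "chain": res.chain_id,
                "number": res.number,
                "icode": res.icode,
                "aa3": res.aa3,
                "in_epitope": res in self.epitope,
                "exposedness": exposed_class.get(res, ""),
                "buried_area_A2": round(buried_by_res.get(res, 0.0), 2),
                "epitope_shared": res in dec.epitope_shared,
                "epitope_interchain": res in dec.epitope_interchain,
                "epitope_intercdr": res in dec.epitope_intercdr,
                "epitope_fw": res in dec.epitope_fw,
                "epitope_extracdr": res in dec.epitope_extracdr,
            }
            for lab, members in dec.epitope_cdr.items():
                row[f"epitope_{lab}"] = res in members
            rows.append(row)
        return pd.DataFrame(rows)

    def to_summary(self) -> dict:
        """JSON-ready scalar summary."""
        inter = self.interaction_counts()
        out = {
            "name": self.name,
            "a_interface": self.a_interface,
            "paratope_size": self.paratope_size,
            "epitope_size": self.epitope_size,
            "heavy_fraction": self.heavy_fraction,
            "cdr_counts": self.cdr_counts(),
            "sub_epitope_sizes": {
                "cdr_individuals": len(self.decomposition.epitope_cdr_individuals),
                "shared": len(self.decomposition.epitope_shared),
                "interchain": len(self.decomposition.epitope_interchain),
                "intercdr": len(self.decomposition.epitope_intercdr),
                "fw": len(self.decomposition.epitope_fw),
                "extracdr": len(self.decomposition.epitope_extracdr),
            },
            "exposedness": self.exposedness.fractions,
            "n_patches": self.patches.n_patches,
            "largest_patch_fraction": self.patches.largest_fraction,
            "n_stretches": len(self.stretches.stretches),
            "longest_stretch": self.stretches.longest,
            "n_hydrophobic_clusters": self.cluster_summary.n_clusters,
            "biggest_cluster_atoms": self.cluster_summary.n_atoms,
            "biggest_cluster_residues": self.cluster_summary.n_residues,
            "interaction_counts": inter,
            "net_charge_paratope": self.charge.net_charge_paratope,
            "net_charge_epitope": self.charge.net_charge_epitope,
            "complementarity": self.charge.complementarity_class,
            "flags": self.flags,
        }
        if self.water_summary.no_water_structure:
            out["interaction_counts"].pop("water_mediated", None)
        return out


def run_complex(cs: ComplexStructure, options: AnalysisOptions | None = None) -> ComplexReport:
    """Execute the full interface characterization of one complex."""
    opt = options or AnalysisOptions()
    flags: list[str] = []

    if opt.max_resolution is not None and cs.resolution is not None:
        if cs.resolution > opt.max_resolution:
            raise ComplexSkipped(
                f"resolution {cs.resolution:.2f} above {opt.max_resolution}"
            )
    ag_residues = cs.residues("antigen")
    if opt.min_ag_residues is not None and len(ag_residues) < opt.min_ag_residues:
        raise ComplexSkipped(
            f"antigen has {len(ag_residues)} residues (< {opt.min_ag_residues})"
        )

    sets = epitope_paratope(cs, opt.probe, opt.n_points, opt.calibration)
    decomposition = decompose_epitope(cs, sets, opt.scheme, opt.probe, opt.n_points)
    exposedness = exposedness_profile(
        cs.ag_atoms, sets.epitope, n_points=opt.exposedness_n_points
    )
    patches = epitope_patches(sets, opt.prune_dist, opt.min_patch_fraction)
    stretches = linear_stretches(sets.epitope, ag_residues, opt.gap_tolerance)

    ss = None
    if opt.dssp_file:
        ss = ss_composition(sets.epitope, opt.dssp_file, ag_residues)

    epi_atoms = cs.atoms_of(sets.epitope)
    para_atoms = cs.atoms_of(sets.paratope)
    clusters = find_hydrophobic_clusters(
        [a for a in epi_atoms if a.is_carbon],
        [a for a in para_atoms if a.is_carbon],
        [a for a in cs.atoms if a.is_polar],
        opt.hydrophobic,
    )
    summary = cluster_stats(clusters, opt.scheme, ss.classes if ss else None)

    # distance criteria alone bound the polar and ring searches, so they
    # run over all heavy atoms of both molecules, not only buried ones
    ab_polar = [a for a in cs.ab_atoms if a.is_polar]
    ag_polar = [a for a in cs.ag_atoms if a.is_polar]
    table = InteractionTable()
    table.extend(detect_salt_bridges(detect_hbonds(ab_polar, ag_polar, opt.polar)))
    waters = cs.waters if opt.keep_waters else []
    water_summary = detect_water_mediated(waters, ab_polar, ag_polar, opt.polar)
    table.extend(water_summary.records)
    if water_summary.no_water_structure:
        flags.append("no_water_structure")

    rings_ab = rings_of(cs.ab_atoms)
    rings_ag = rings_of(cs.ag_atoms)
    table.extend(detect_pi_pi(rings_ab, rings_ag, opt.rings))
    charged = [
        a for a in cs.atoms
        if classify_chemistry(a).cationic or classify_chemistry(a).anionic
    ]
    table.extend(detect_pi_ion(rings_ab + rings_ag, charged, opt.rings))

    # role classification is an interface property: restricted to the
    # polar atoms of epitope/paratope residues
    _, role_dist = polar_roles(
        [a for a in para_atoms + epi_atoms if a.is_polar],
        table,
        clusters.shielding_attributions,
    )
    role_profiles = residue_role_profiles(
        sets.paratope | sets.epitope, table, clusters
    )
    charge = charge_profile(sets.paratope, sets.epitope, opt.pH, opt.pka_table)

    if not sets.epitope:
        flags.append("empty_epitope")
    return ComplexReport(
        name=cs.name,
        a_interface=sets.A_interface,
        epitope=sets.epitope,
        paratope=sets.paratope,
        sets=sets,
        decomposition=decomposition,
        exposedness=exposedness,
        patches=patches,
        stretches=stretches,
        ss=ss,
        clusters=clusters,
        cluster_summary=summary,
        interactions=table,
        water_summary=water_summary,
        polar_role_distribution=role_dist,
        role_profiles=role_profiles,
        charge=charge,
        flags=flags,
    )


@dataclass
class AggregateReport:
    """Mean +/- sd descriptors and pooled compositions across complexes.

    The standard deviation is the population sd (a singleton aggregates to
    sd 0); amino-acid compositions are pooled over residues.
    """

    n_complexes: int
    descriptors: dict[str, tuple[float, float]]
    aa_composition: dict[str, dict[str, float]]
    interaction_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_complexes": self.n_complexes,
            "descriptors": {
                k: {"mean": m, "sd": s} for k, (m, s) in self.descriptors.items()
            },
            "aa_composition": self.aa_composition,
            "interaction_means": self.interaction_means,
        }


def aggregate(reports: list[ComplexReport]) -> AggregateReport:
    """Unweighted per-complex aggregation of all scalar descriptors."""
    if not reports:
        raise ValueError("need at least one report")
    per_complex = [r.scalars() for r in reports]
    desc: dict[str, tuple[float, float]] = {}
    for key in per_complex[0]:
        vals = np.array([s[key] for s in per_complex], dtype=float)
        desc[key] = (float(vals.mean()), float(vals.std(ddof=0)))

    pooled: dict[str, Counter] = {
        "paratope": Counter(), "epitope": Counter(), "ag_surface": Counter()
    }
    for r in reports:
        pooled["paratope"].update(res.aa3 for res in r.paratope)
        pooled["epitope"].update(res.aa3 for res in r.epitope)
        pooled["ag_surface"].update(
            res.aa3 for res in r.sets.ag_surface_residues
        )
    composition = {}
    for cat, counts in pooled.items():
        total = sum(counts.values())
        composition[cat] = (
            {aa: c / total for aa, c in sorted(counts.items())} if total else {}
        )

    inter_sums: dict[str, float] = defaultdict(float)
    inter_n: dict[str, int] = defaultdict(int)
    for r in reports:
        counts = r.interaction_counts()
        for kind in ("hbond", "salt_bridge", "pi_pi", "pi_cation", "pi_anion"):
            inter_sums[kind] += counts.get(kind, 0)
            inter_n[kind] += 1
        if not r.water_summary.no_water_structure:
            inter_sums["water_mediated"] += counts.get("water_mediated", 0)
            inter_n["water_mediated"] += 1
    means = {
        k: (inter_sums[k] / inter_n[k]) for k in inter_sums if inter_n[k]
    }
    return AggregateReport(
        n_complexes=len(reports),
        descriptors=desc,
        aa_composition=composition,
        interaction_means=means,
    )


def run_manifest(
    manifest_csv,
    out_dir,
    options: AnalysisOptions | None = None,
) -> tuple[list[ComplexReport], AggregateReport | None]:
    """Analyze every complex listed in a manifest CSV.

    Columns: ``pdb_path,heavy,light,antigen`` (antigen chains joined by
    ``+``).  Failing complexes are skipped and logged; the run continues.
    """
    opt = options or AnalysisOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    with open(manifest_csv, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        name = Path(row["pdb_path"]).stem
        try:
            cs = read_complex(
                row["pdb_path"],
                (row["heavy"], row["light"]),
                set(row["antigen"].split("+")),
                keep_waters=opt.keep_waters,
            )
            report = run_complex(cs, opt)
        except ComplexSkipped as exc:
            log.info("complex=%s stage=filter outcome=skipped reason=%s", name, exc)
            continue
        except Exception as exc:
            log.warning("complex=%s stage=analysis outcome=error reason=%s", name, exc)
            continue
        log.info("complex=%s stage=analysis outcome=ok", name)
        reports.append(report)
        with open(out_dir / f"{name}.json", "w") as fh:
            json.dump(report.to_summary(), fh, indent=1, default=str)
        report.to_residue_table().to_csv(
            out_dir / f"{name}.residues.csv", index=False
        )
        report.interactions.to_dataframe().to_csv(
            out_dir / f"{name}.interactions.csv", index=False
        )
    agg = aggregate(reports) if reports else None
    if agg:
        with open(out_dir / "aggregate.json", "w") as fh:
            json.dump(agg.to_dict(), fh, indent=1)
    return reports, agg
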