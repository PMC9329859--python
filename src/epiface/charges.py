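"""Net-charge estimation of epitope and paratope from per-site pKa values.

Charges follow the Henderson-Hasselbalch fractional model: an acid
contributes ``-1 / (1 + 10**(pKa - pH))`` and a base ``+1 / (1 + 10**(pH -
pKa))``.  Site pKa values are ingested from a table (computed upstream by a
continuum-electrostatics tool); sites without an entry fall back to
reference values measured on capped alanine-based pentapeptides.  Arg is
included as a base (essentially fully charged at physiological pH);
termini are excluded: only side chains titrate here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .structures import ResidueKey

#: Reference side-chain pKa values on the pentapeptide scale.
REFERENCE_PKA: dict[str, float] = {
    "ASP": 3.9,
    "GLU": 4.3,
    "HIS": 6.5,
    "CYS": 8.6,
    "TYR": 9.8,
    "LYS": 10.4,
    "ARG": 12.3,
}

ACID_TYPES = {"ASP", "GLU", "CYS", "TYR", "CTR"}
BASE_TYPES = {"HIS", "LYS", "ARG", "NTR"}


class PkaTableError(ValueError):
    """A malformed row in a per-site pKa table."""


@dataclass(frozen=True)
class TitratableSite:
    """One titratable side chain with its (possibly shifted) pKa."""

    residue: ResidueKey
    site_type: str
    pka: float
    reference_pka: float

    @property
    def is_acid(self) -> bool:
        return self.site_type in ACID_TYPES

    @property
    def shift(self) -> float:
        return self.pka - self.reference_pka

    def charge(self, pH: float) -> float:
        if self.is_acid:
            return -1.0 / (1.0 + 10.0 ** (self.pka - pH))
        return 1.0 / (1.0 + 10.0 ** (pH - self.pka))


def load_pka(pka_file) -> dict[tuple[str, int, str, str], float]:
    """Read a per-site pKa table: CSV columns (chain, resnum, icode, site, pka).

    Returns a mapping keyed by ``(chain, resnum, icode, site_type)``.
    Malformed rows raise :class:`PkaTableError` naming the row.
    """
    table: dict[tuple[str, int, str, str], float] = {}
    with open(pka_file, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].strip().startswith("#"):
                continue
            if row[0].strip().lower() == "chain":
                continue  # header
            try:
                chain, resnum, icode, site, pka = (c.strip() for c in row[:5])
                table[(chain, int(resnum), icode, site.upper())] = float(pka)
            except (ValueError, IndexError) as exc:
                raise PkaTableError(f"malformed pKa row {i}: {row!r}") from exc
    return table


def titratable_sites(
    residues,
    pka_table: dict[tuple[str, int, str, str], float] | None = None,
) -> list[TitratableSite]:
    """Build sites for every titratable residue, with table/fallback pKa.

    Provenance: a site uses the table value when ``(chain, number, icode,
    aa3)`` is present, otherwise the pentapeptide reference.
    """
    sites = []
    for res in sorted(residues):
        ref = REFERENCE_PKA.get(res.aa3)
        if ref is None:
            continue
        key = (res.chain_id, res.number, res.icode, res.aa3)
        pka = (pka_table or {}).get(key, ref)
        sites.append(TitratableSite(res, res.aa3, pka, ref))
    return sites


def net_charge(sites: list[TitratableSite], pH: float) -> float:
    """Fractional net charge of a site set at the given pH."""
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must be in [0, 14]")
    return sum(s.charge(pH) for s in sites)


def complementarity(qp: float, qe: float) -> str:
    """Charge-complementarity class from rounded integer net charges."""
    rp, re = round(qp), round(qe)
    if rp == 0 and re == 0:
        return "both_neutral"
    if rp == 0 or re == 0:
        return "one_neutral"
    return "opposite" if (rp > 0) != (re > 0) else "same"


@dataclass
class ChargeProfile:
    """Net interface charges at one pH and their complementarity class."""

    pH: float
    net_charge_paratope: float
    net_charge_epitope: float
    complementarity_class: str
    paratope_sites: list[TitratableSite]
    epitope_sites: list[TitratableSite]


def charge_profile(
    paratope_residues,
    epitope_residues,
    pH: float = 7.2,
    pka_table=None,
) -> ChargeProfile:
    psites = titratable_sites(paratope_residues, pka_table)
    esites = titratable_sites(epitope_residues, pka_table)
    qp = net_charge(psites, pH)
    qe = net_charge(esites, pH)
    return ChargeProfile(
        pH=pH,
        net_charge_paratope=qp,
        net_charge_epitope=qe,
        complementarity_class=complementarity(qp, qe),
        paratope_sites=psites,
        epitope_sites=esites,
    )
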