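"""Chemical-shift perturbation (CSP) mapping between methyl peak lists.

Peak positions of methyl 1H-13C cross-peaks are compared between a reference
spectrum (e.g. the free enzyme) and a comparison spectrum (ligand-bound or
mutant).  Per-axis displacements are combined into a single dimensionless
perturbation magnitude

    dCS = sqrt((ddH / cH)^2 + (ddC / cC)^2)

where the per-methyl-class constants (cH, cC) are the standard deviations of
assigned methyl shifts in the BMRB: (0.28, 1.66) ppm for Ile-d1 and
(0.38, 1.67) ppm for Met-e.  Constants for other methyl classes are not
built in and must be supplied explicitly.

Site matching is by assignment label (e.g. ``I45``); nearest-peak matching
of unassigned peaks is out of scope.  Peaks present in the reference but
absent in the comparison list are flagged ``disappeared`` (severe-exchange
broadening behaves this way), and vice versa ``new``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DELTA_CS_CONSTANTS",
    "Peak",
    "PeakList",
    "delta_cs",
    "perturbation_table",
]

#: (cH, cC) normalisation constants in ppm per methyl class
DELTA_CS_CONSTANTS: dict[str, tuple[float, float]] = {
    "Ile-d1": (0.28, 1.66),
    "Met-e": (0.38, 1.67),
}

_CLASS_BY_RESIDUE_LETTER = {
    "I": "Ile-d1",
    "M": "Met-e",
    "L": "Leu-d",
    "V": "Val-g",
}

_METHYL_ATOMS = {
    "Ile-d1": ("CD1", "HD1"),
    "Met-e": ("CE", "HE"),
    "Leu-d": ("CD1", "HD1"),
    "Val-g": ("CG1", "HG1"),
}


@dataclass(frozen=True)
class Peak:
    """One assigned methyl cross-peak."""

    site: str  # e.g. "I45"
    methyl_class: str  # one of Ile-d1, Met-e, Leu-d, Val-g
    dh: float  # 1H shift, ppm
    dc: float  # 13C shift, ppm
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dh) and np.isfinite(self.dc)):
            raise ValueError(f"non-finite shifts for {self.site}")
        if self.methyl_class not in _METHYL_ATOMS:
            raise ValueError(f"unknown methyl class {self.methyl_class!r}")


def classify_site(site: str) -> str:
    """Methyl class inferred from the residue one-letter code of a site id."""
    letter = site[0].upper()
    try:
        return _CLASS_BY_RESIDUE_LETTER[letter]
    except KeyError:
        raise ValueError(f"cannot infer methyl class for site {site!r}") from None


class PeakList:
    """Ordered collection of assigned peaks, indexed by site id."""

    def __init__(self, peaks: Iterable[Peak] = ()):
        self._peaks: dict[str, Peak] = {}
        for p in peaks:
            if p.site in self._peaks:
                raise ValueError(f"duplicate site {p.site}")
            self._peaks[p.site] = p

    def __len__(self) -> int:
        return len(self._peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks.values())

    def __contains__(self, site: str) -> bool:
        return site in self._peaks

    def __getitem__(self, site: str) -> Peak:
        return self._peaks[site]

    def sites(self) -> list[str]:
        return list(self._peaks)

    def add(self, peak: Peak) -> None:
        self._peaks[peak.site] = peak

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_sparky(cls, path: str | Path) -> "PeakList":
        """Read a Sparky ``.list`` file (Assignment  w1  w2  [Height]).

        w1 is the 13C shift and w2 the 1H shift, in ppm.  Assignment labels
        like ``I45CD1-HD1`` are reduced to the site id ``I45``.
        """
        peaks = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            m = re.match(r"([A-Za-z])(\d+)", parts[0])
            if not m:
                raise ValueError(f"cannot parse assignment label {parts[0]!r}")
            site = m.group(1).upper() + m.group(2)
            w1, w2 = float(parts[1]), float(parts[2])
            height = float(parts[3]) if len(parts) > 3 else 1.0
            peaks.append(Peak(site, classify_site(site), dh=w2, dc=w1, intensity=height))
        return cls(peaks)

    def to_sparky(self, path: str | Path) -> None:
        lines = [f"{'Assignment':>12} {'w1':>9} {'w2':>9} {'Height':>13}"]
        for p in self:
            catom, hatom = _METHYL_ATOMS[p.methyl_class]
            label = f"{p.site}{catom}-{hatom}"
            lines.append(f"{label:>12} {p.dc:9.3f} {p.dh:9.3f} {p.intensity:13.5e}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakList":
        """Read a CSV peak list with columns site, dh_ppm, dc_ppm[, intensity]."""
        frame = pd.read_csv(path)
        return cls.from_frame(frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeakList":
        peaks = []
        for _, row in frame.iterrows():
            site = str(row["site"])
            mclass = row.get("methyl_class") or classify_site(site)
            peaks.append(
                Peak(
                    site,
                    str(mclass),
                    dh=float(row["dh_ppm"]),
                    dc=float(row["dc_ppm"]),
                    intensity=float(row.get("intensity", 1.0)),
                )
            )
        return cls(peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": p.site,
                    "methyl_class": p.methyl_class,
                    "dh_ppm": p.dh,
                    "dc_ppm": p.dc,
                    "intensity": p.intensity,
                }
                for p in self
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def delta_cs(
    methyl_class: str,
    ddh: float,
    ddc: float,
    constants: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Normalised shift-perturbation magnitude for one methyl class.

    Raises for classes without built-in constants (Leu/Val) unless the
    caller supplies them via ``constants``.
    """
    table = dict(DELTA_CS_CONSTANTS)
    if constants:
        table.update(constants)
    if methyl_class not in table:
        raise ValueError(
            f"no dCS normalisation constants for methyl class {methyl_class!r}; "
            "supply (cH, cC) explicitly"
        )
    ch, cc = table[methyl_class]
    return float(np.hypot(ddh / ch, ddc / cc))


def perturbation_table(
    reference: PeakList,
    comparison: PeakList,
    constants: Mapping[str, tuple[float, float]] | None = None,
    flag_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-site shift perturbations between two peak lists.

    Shared sites get ddH, ddC, dCS and the intensity ratio; reference-only
    sites are flagged ``disappeared`` and comparison-only sites ``new``.
    Sites with dCS above mean + ``flag_sd``*SD of the shared-site values are
    marked ``affected`` (a ranking aid; no significance threshold implied).
    Raises when the two lists share no site.
    """
    shared = [s for s in reference.sites() if s in comparison]
    if not shared:
        raise ValueError("peak lists share no site identifiers")
    rows = []
    for s in shared:
        a, b = reference[s], comparison[s]
        ddh = b.dh - a.dh
        ddc = b.dc - a.dc
        rows.append(
            {
                "site": s,
                "methyl_class": a.methyl_class,
                "ddh_ppm": ddh,
                "ddc_ppm": ddc,
                "delta_cs": delta_cs(a.methyl_class, ddh, ddc, constants),
                "intensity_ratio": b.intensity / a.intensity if a.intensity else np.nan,
                "disappeared": False,
                "new": False,
            }
        )
    for s in reference.sites():
        if s not in comparison:
            p = reference[s]
            rows.append(
                {
                    "site": s,
                    "methyl_class": p.methyl_class,
                    "ddh_ppm": np.nan,
                    "ddc_ppm": np.nan,
                    "delta_cs": np.nan,
                    "intensity_ratio": 0.0,
                    "disappeared": True,
                    "new": False,
                }
            )
    for s in comparison.sites():
        if s not in reference:
            p = comparison[s]
            rows.append(
                {
                    "site": s,
                    "methyl_class": p.methyl_class,
                    "ddh_ppm": np.nan,
                    "ddc_ppm": np.nan,
                    "delta_cs": np.nan,
                    "intensity_ratio": np.nan,
                    "disappeared": False,
                    "new": True,
                }
            )
    table = pd.DataFrame(rows)
    vals = table.loc[~table["disappeared"] & ~table["new"], "delta_cs"]
    cutoff = vals.mean() + flag_sd * vals.std(ddof=0) if len(vals) else np.inf
    table["affected"] = table["delta_cs"] > cutoff
    table.attrs["delta_cs_cutoff"] = float(cutoff) if np.isfinite(cutoff) else None
    return table.sort_values("delta_cs", ascending=False, ignore_index=True)


def attribute_file(table: pd.DataFrame, attribute: str = "deltaCS") -> str:
    """Residue-keyed attribute text for structure-viewer colouring."""
    lines = [f"attribute: {attribute}", "match mode: any", "recipient: residues"]
    for _, row in table.iterrows():
        if np.isfinite(row["delta_cs"]):
            resnum = re.match(r"[A-Za-z]+(\d+)", row["site"]).group(1)
            lines.append(f"\t:{resnum}\t{row['delta_cs']:.4f}")
    return "\n".join(lines) + "\n"
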