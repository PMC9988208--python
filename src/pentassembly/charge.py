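"""Net charge of the pentapeptide versus pH, and counterion bookkeeping.

The titratable sites of CREKA / CRE(NMe)KA and their pKa values:
Glu side chain 4.2 (acid), Arg side chain 12.5 (base), Lys side chain 10.5
(base), N-terminal ammonium ~8 (base), C-terminal carboxylate ~3 (acid).
Under the dominant-state rule a site is protonated iff pH < pKa (strict);
an acid contributes 0 when protonated and -1 when deprotonated, a base +1
when protonated and 0 when deprotonated.  This yields the charge ladder
+2 at pH 4, +1 at pH 7 and 0 at pH 10.

The Cys thiol (pKa ~8.3) is excluded from the default site set: the charge
ladder above treats it as non-titrating over pH 4-10.  Enable it explicitly
via ``default_sites(include_cys=True)`` if needed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .errors import ParameterError


class SiteKind(enum.Enum):
    ACID = "acid"  # neutral <-> -1
    BASE = "base"  # +1 <-> neutral


@dataclass(frozen=True)
class IonizableSite:
    name: str
    pKa: float
    kind: SiteKind

    def __post_init__(self) -> None:
        if not (self.pKa == self.pKa and abs(self.pKa) < 1e6):
            raise ParameterError(f"site {self.name}: pKa must be finite")


def default_sites(include_cys: bool = False) -> list[IonizableSite]:
    sites = [
        IonizableSite("Glu-side", 4.2, SiteKind.ACID),
        IonizableSite("Arg-side", 12.5, SiteKind.BASE),
        IonizableSite("Lys-side", 10.5, SiteKind.BASE),
        IonizableSite("N-term", 8.0, SiteKind.BASE),
        IonizableSite("C-term", 3.0, SiteKind.ACID),
    ]
    if include_cys:
        sites.append(IonizableSite("Cys-side", 8.3, SiteKind.ACID))
    return sites


@dataclass(frozen=True)
class ChargeProfile:
    pH: float
    per_site_charge: dict
    net: int

    def to_dict(self) -> dict:
        return {"pH": self.pH, "per_site": dict(self.per_site_charge), "net": self.net}


def _check_ph(pH: float) -> None:
    if not 0.0 <= pH <= 14.0:
        warnings.warn(f"pH {pH} outside the aqueous 0-14 range", stacklevel=3)


def dominant_charge(pH: float, sites: list[IonizableSite] | None = None) -> ChargeProfile:
    """Integer net charge under the dominant-protonation-state rule.

    A site is protonated iff pH < pKa (ties resolve as deprotonated).
    """
    if sites is None:
        sites = default_sites()
    if not sites:
        raise ParameterError("site list must be non-empty")
    _check_ph(pH)
    per_site = {}
    for s in sites:
        protonated = pH < s.pKa
        if s.kind is SiteKind.ACID:
            per_site[s.name] = 0 if protonated else -1
        else:
            per_site[s.name] = 1 if protonated else 0
    return ChargeProfile(pH=pH, per_site_charge=per_site, net=sum(per_site.values()))


def fractional_charge(pH: float, sites: list[IonizableSite] | None = None) -> float:
    """Henderson-Hasselbalch mean net charge: continuous, non-increasing in pH.

    An acid contributes -1/(1+10^(pKa-pH)); a base +1/(1+10^(pH-pKa)).
    """
    if sites is None:
        sites = default_sites()
    if not sites:
        raise ParameterError("site list must be non-empty")
    _check_ph(pH)
    net = 0.0
    for s in sites:
        if s.kind is SiteKind.ACID:
            net -= 1.0 / (1.0 + 10.0 ** (s.pKa - pH))
        else:
            net += 1.0 / (1.0 + 10.0 ** (pH - s.pKa))
    return net


def counterions_needed(
    n_chains: int, pH: float, sites: list[IonizableSite] | None = None
) -> tuple[str, int]:
    """Counterions neutralising ``n_chains`` chains at the given pH.

    One ion per unit of dominant net charge per chain: chloride for positive
    peptides, sodium for negative, none at zero net charge.
    """
    if n_chains < 0:
        raise ParameterError("n_chains must be >= 0")
    net = dominant_charge(pH, sites).net
    if net > 0:
        return "chloride", n_chains * net
    if net < 0:
        return "sodium", n_chains * (-net)
    return "none", 0
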