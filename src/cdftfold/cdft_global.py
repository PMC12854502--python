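"""Global reactivity descriptors from frontier-orbital energies.

Under the frozen orbital approximation the ionization potential and
electron affinity are estimated from the frontier MO energies
(IP = −E_HOMO, EA = −E_LUMO), and the remaining descriptors follow:

* chemical potential  μ = (E_HOMO + E_LUMO) / 2
* hardness            η = E_LUMO − E_HOMO  (= IP − EA)
* softness            S = 1 / η
* electrophilicity    ω = μ²·S / 2
* nMax                nMax = −μ / η  (maximum electron acceptance)

All quantities are in eV except S (1/eV) and nMax (dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass

from .qm_io import ElectronicStructure

__all__ = ["GlobalDescriptors", "global_descriptors"]


@dataclass(frozen=True)
class GlobalDescriptors:
    ip: float          # eV
    ea: float          # eV
    mu: float          # eV
    eta: float         # eV
    softness: float    # 1/eV
    omega: float       # eV
    n_max: float       # dimensionless
    frame_id: str | int | None = None


def global_descriptors(es: ElectronicStructure,
                       frame_id=None) -> GlobalDescriptors:
    """Compute the seven global descriptors for one frame.

    Raises
    ------
    ValueError
        If the system has no virtual MO ("no LUMO") or a non-positive
        HOMO–LUMO gap.
    """
    try:
        e_lumo = es.e_lumo
    except ValueError as exc:
        raise ValueError("no LUMO") from exc
    e_homo = es.e_homo
    gap = e_lumo - e_homo
    if gap <= 0:
        raise ValueError(f"non-positive gap: E_LUMO − E_HOMO = {gap:.6f} eV")
    mu = 0.5 * (e_homo + e_lumo)
    softness = 1.0 / gap
    return GlobalDescriptors(
        ip=-e_homo,
        ea=-e_lumo,
        mu=mu,
        eta=gap,
        softness=softness,
        omega=0.5 * mu * mu * softness,
        n_max=-mu / gap,
        frame_id=frame_id,
    )
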