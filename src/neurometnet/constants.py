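"""Physiological flux constraints for the stimulated glutamatergic synapse.

All rates are in micromolar per second (uM/s) and come from real-time
FRET/dye measurements in neuron-astrocyte co-cultures: sodium is extruded
at 350 uM/s after stimulation, the Na/K-ATPase pump hydrolyses one ATP per
three sodium ions exported, housekeeping ATP turnover is 38 uM/s, resting
neuronal glucose consumption is 0.9 uM/s and rises 2.353-fold upon
stimulation, astrocytic oxygen uptake in co-culture is 0.01666 uM/s, and
complete glucose oxidation yields 31 ATP per glucose.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluxConstraints:
    """Default flux constraints of the stimulated neuron-astrocyte system.

    Attributes
    ----------
    sodium_efflux : float
        Neuronal Na+ extrusion rate after stimulation (uM/s).
    sodium_per_atp : float
        Na+ ions exported per ATP hydrolysed by the Na/K-ATPase pump.
    housekeeping_atp : float
        Stimulus-independent neuronal ATP demand (uM/s).
    resting_glucose : float
        Resting neuronal glucose consumption (uM/s).
    stimulation_fold : float
        Fold-increase of the neuronal glycolytic rate upon stimulation.
    astrocytic_oxygen_uptake : float
        Fixed astrocytic O2 uptake in co-culture (uM/s).
    atp_per_glucose : float
        ATP yield of complete glucose oxidation (mol/mol).
    total_atp_demand : float
        Total neuronal ATP demand to re-establish ion gradients (uM/s).
    glutamate_cycle_capacity : float
        Capacity of the glutamate-glutamine cycle, applied at the
        astrocyte-specific glutamine synthetase step (uM/s).
    glycogenolysis_capacity : float
        Capacity of astrocytic glycogen-derived glucose release (uM/s).
    """

    sodium_efflux: float = 350.0
    sodium_per_atp: float = 3.0
    housekeeping_atp: float = 38.0
    resting_glucose: float = 0.9
    stimulation_fold: float = 2.353
    astrocytic_oxygen_uptake: float = 0.01666
    atp_per_glucose: float = 31.0
    total_atp_demand: float = 155.0
    glutamate_cycle_capacity: float = 4.138
    glycogenolysis_capacity: float = 0.3

    @property
    def pump_atp_demand(self) -> float:
        """ATP consumption implied by the sodium efflux rate (uM/s)."""
        return self.sodium_efflux / self.sodium_per_atp

    @property
    def stimulated_glycolysis(self) -> float:
        """Stimulated neuronal glycolytic rate (uM/s)."""
        return self.resting_glucose * self.stimulation_fold

    @property
    def glycolytic_atp_supply(self) -> float:
        """ATP produced by fully oxidising the stimulated glycolytic flux."""
        return self.stimulated_glycolysis * self.atp_per_glucose

    @property
    def derived_total_atp_demand(self) -> float:
        """Housekeeping plus pump ATP demand (uM/s)."""
        return self.housekeeping_atp + self.pump_atp_demand


DEFAULT_CONSTRAINTS = FluxConstraints()
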