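"""hofaudit: audit of energy-minimized protein geometries against X-ray
structures.

The package ingests heat-of-formation records for protein structures
before and after full geometry optimization, computes per-atom
energy-change statistics, partitions them orthogonally into a
method-error component and an experimental/environmental component,
and validates optimized geometries through van der Waals clash
detection and rigid potential-energy-surface scans.  A surrogate force
field and synthetic-structure generators make every stage testable
without a quantum-chemistry engine.
"""

from importlib import resources

from .structure import (
    AtomRecord,
    MolecularStructure,
    read_pdb,
    write_pdb,
    infer_bonds,
    count_atoms,
)
from .energy import (
    GAS,
    AQUEOUS,
    PhaseEnergyRecord,
    EnergyBackend,
    SurrogateParams,
    SurrogateForceField,
    read_energy_table,
    write_energy_table,
)
from .partition import (
    DEFAULT_METHOD_ERROR,
    PartitionConstants,
    PartitionResult,
    CohortSummary,
    total_epsilon,
    partition,
    partition_record,
    partition_records,
    summarize,
    results_to_frame,
)
from .hydrogenation import (
    ProtonationTemplates,
    load_default_templates,
    strip_hydrogens,
    add_hydrogens,
    optimize_hydrogen_positions,
)
from .calibration import (
    BenchmarkSystem,
    read_benchmark_file,
    filter_systems,
    method_error_estimate,
)
from .clash import (
    ClashRecord,
    ClashReport,
    find_clashes,
    min_interresidue_h_distance,
)
from .pes import ScanSpec, PESProfile, default_grid, rigid_scan, locate_minimum
from .synthetic import (
    PerturbationSpec,
    make_polyalanine,
    make_two_chain_complex,
    make_probe_pair,
    make_clash_fixture,
    perturb,
    rmsd,
    relaxation_trajectory,
    make_energy_fixture,
)

__version__ = "0.1.0"


def packaged_energy_table() -> list[PhaseEnergyRecord]:
    """The packaged 19-protein heat-of-formation table."""
    with resources.as_file(resources.files("hofaudit.data") / "hof_table.csv") as p:
        return read_energy_table(p)
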