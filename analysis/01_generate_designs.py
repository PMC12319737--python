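"""Generate the task designs used throughout the analysis.

Builds pseudorandomized, timed block designs for tasks A and B (2 blocks of
48 trials each), validates every constraint, and writes them to
results/designs/.
"""

from pathlib import Path

from fbl_rlddm.simulate import make_task_designs
from fbl_rlddm.task_design import validate_design, write_design_tsv

OUT = Path(__file__).resolve().parent.parent / "results" / "designs"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for task in ("A", "B"):
        designs = make_task_designs(task, n_blocks=2, rng_seed=SEED)
        for d in designs:
            report = validate_design(d)
            assert all(report.values()), (task, d.block, report)
        write_design_tsv(designs, OUT / f"task_{task}_design.tsv")
        print(f"task {task}: 2 blocks x 48 trials, all pseudorandomization "
              "constraints satisfied")
    print(f"designs written to {OUT}")


if __name__ == "__main__":
    main()
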