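"""Generate the synthetic benchmark that stands in for a structural interactome.

Writes partner interface maps (with planted competitive cliques around
designated hub proteins), expression profiles with planted pair correlations,
and annotation tables with planted species-specific domains, plus the ground
truth, to results/synthetic/.
"""

from pathlib import Path

from ccrn.synthetic_data import GeneratorConfig, write_benchmark

# regenerable bulk input: kept out of results/, under the scratch area
OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    config = GeneratorConfig(seed=0)
    paths = write_benchmark(config, OUT)
    print(f"synthetic benchmark written to {OUT}")
    for name, path in sorted(paths.items()):
        print(f"  {name:18s} {path.name}")


if __name__ == "__main__":
    main()
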