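"""Regenerate the canonical figure tables with a verification manifest.

Equivalent to `armstat reproduce`; writes the trace-family,
torque-wave, and synergy-weight CSVs plus manifest.json into an output
directory and prints the manifest verdict.
"""

from armstat import RunConfig, reproduce

config = RunConfig(out_dir="scratch/reproduced")
manifest = reproduce(config)

print(f"wrote tables to {config.out_dir}/")
for entry in manifest.entries:
    mark = "ok " if entry.passed else "FAIL"
    print(f"  [{mark}] {entry.name}: computed {entry.computed:.12g} "
          f"(expected {entry.expected:.12g})")
print(f"all constants verified: {manifest.all_passed}")
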