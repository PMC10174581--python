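# Original carbon-flux webs (not redistributed)

The full-replication integration test and `kweb compare` expect the
twelve empirical carbon-flux food webs here as canonical JSON, one file
per web (`*.json`).  The webs are distributed with the enaR ecological
network analysis collection and as supplementary data of the robustness
literature; they are not redistributed in this repository.

To convert a supplementary-style JSON file whose keys differ from the
canonical schema, write a YAML mapping from canonical keys
(`species`, `flows`, `imports`, `exports`, `respiration`, optionally
`name`) to the source file's key names and load it through the adapter:

```sh
kweb info source.json --s1-map mapping.yaml
```

then re-export with `kweb.write_foodweb_json` or keep using `--s1-map`
directly on every subcommand.
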