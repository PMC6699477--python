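# Published genome records

The acceptance tests for published-genome reproduction
(`tests/test_acceptance.py::test_criterion_3_accession_reproduction` and
`::test_criterion_4_real_data_tallies`) read GenBank flat files from this
directory:

- `CP016327.gb` — *Candidatus* Portiera aleyrodidarum, host cryptic species Asia II 3 ("Z1")
- `CP016343.gb` — *Ca.* Portiera aleyrodidarum, host cryptic species China 1 ("Z3")
- `CP003708.gb` — *Ca.* Portiera aleyrodidarum BT-B
- `CP003835.gb` — *Ca.* Portiera aleyrodidarum BT-QVLC

They are not bundled (large, externally versioned). With network access,
fetch them with e.g.:

```sh
for acc in CP016327 CP016343 CP003708 CP003835; do
  curl -o data/accessions/$acc.gb \
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=$acc&rettype=gbwithparts&retmode=text"
done
```

Without these files the two tests fail with a message pointing here; every
other test runs fully offline.
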