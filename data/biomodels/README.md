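# BioModels inputs (optional, not bundled)

The paper-scale checks use three curated kinetic models from the BioModels
database. They are not redistributed here; download the SBML files and place
them in this directory under these exact names:

- `BIOMD0000000023.xml` — sucrose accumulation, *Saccharum officinarum*
  (https://www.ebi.ac.uk/biomodels/BIOMD0000000023)
- `BIOMD0000000042.xml` — glycolysis, *Saccharomyces cerevisiae*
  (https://www.ebi.ac.uk/biomodels/BIOMD0000000042)
- `BIOMD0000000066.xml` — threonine synthesis, *Escherichia coli*
  (https://www.ebi.ac.uk/biomodels/BIOMD0000000066)

Everything else in the package (including the full benchmark) runs on
synthetic networks and needs no downloads.
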