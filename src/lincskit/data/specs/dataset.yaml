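# Dataset metadata specification: a single category of exactly 37
# non-experimental descriptors covering identification, attribution,
# provenance and release properties of a dataset.
family: dataset
version: "1.0"
common_fields: []
categories:
  - name: Dataset
    fields:
      - {name: Dataset Identifier, importance: 1, value_kind: identifier,
         description: Persistent LDS identifier, provenance: published}
      - {name: Dataset Group Identifier, importance: 1, value_kind: identifier,
         description: Persistent LDG identifier of the parent group,
         provenance: implementer-defined}
      - {name: Dataset Title, importance: 1, value_kind: text,
         description: Human-readable dataset title, provenance: implementer-defined}
      - {name: Dataset Description, importance: 2, value_kind: text,
         description: Abstract-level description, provenance: implementer-defined}
      - {name: PI Name, importance: 1, value_kind: text,
         description: Principal investigator, provenance: published}
      - {name: PI Email, importance: 2, value_kind: text,
         description: Contact address of the PI, provenance: implementer-defined}
      - {name: Center Name, importance: 1, value_kind: text,
         description: Producing center, provenance: published}
      - {name: Center URL, importance: 3, value_kind: url,
         description: Center home page, provenance: implementer-defined}
      - {name: Grant Number, importance: 1, value_kind: text,
         description: Funding grant number, provenance: published}
      - {name: Funding Agency, importance: 2, value_kind: text,
         description: Agency funding the work, provenance: implementer-defined}
      - {name: Assay Name, importance: 1, value_kind: text,
         description: Assay that produced the data, provenance: implementer-defined}
      - {name: Assay Description, importance: 3, value_kind: text,
         description: Short description of the assay, provenance: implementer-defined}
      - {name: Data Level, importance: 1, value_kind: integer,
         description: Harmonized data level (1 raw through 4+ signature),
         provenance: implementer-defined}
      - {name: Data Level Role, importance: 2, value_kind: vocabulary,
         vocabulary_ref: data_level_role,
         description: Role vocabulary for levels 1-4,
         provenance: implementer-defined}
      - {name: Dataset Release Date, importance: 1, value_kind: date,
         description: Public release date, provenance: published}
      - {name: Dataset Version, importance: 1, value_kind: text,
         description: Release version label, provenance: implementer-defined}
      - {name: Date Updated, importance: 3, value_kind: date,
         description: Last metadata update, provenance: implementer-defined}
      - {name: Processing Pipeline, importance: 2, value_kind: url,
         description: Link to the pipeline transforming raw data to this level,
         provenance: published}
      - {name: Processing Pipeline Version, importance: 3, value_kind: text,
         description: Pipeline version used, provenance: implementer-defined}
      - {name: QC Information, importance: 2, value_kind: text,
         description: Quality-control standards and outcomes,
         provenance: published}
      - {name: SOP Reference, importance: 3, value_kind: url,
         description: Standard operating procedure link,
         provenance: implementer-defined}
      - {name: File Format, importance: 2, value_kind: text,
         description: Format of the payload files, provenance: implementer-defined}
      - {name: File Count, importance: 3, value_kind: integer,
         description: Number of payload files, provenance: implementer-defined}
      - {name: Total Size, importance: 3, value_kind: decimal,
         description: Payload size in megabytes, provenance: implementer-defined}
      - {name: Checksum Algorithm, importance: 3, value_kind: text,
         description: Digest algorithm used in the manifest,
         provenance: implementer-defined}
      - {name: Reagent Categories Used, importance: 2, value_kind: text,
         description: Reagent categories appearing in the experiments,
         provenance: implementer-defined}
      - {name: Number of Experiments, importance: 3, value_kind: integer,
         description: Experiments contributing to the dataset,
         provenance: implementer-defined}
      - {name: Organism, importance: 2, value_kind: text,
         description: Organism of the model systems, provenance: implementer-defined}
      - {name: Keywords, importance: 3, value_kind: text,
         description: Search keywords, provenance: implementer-defined}
      - {name: License, importance: 2, value_kind: text,
         description: Data reuse license, provenance: implementer-defined}
      - {name: Repository, importance: 2, value_kind: text,
         description: Repository hosting the package, provenance: implementer-defined}
      - {name: Resource Type, importance: 2, value_kind: text,
         description: Resource type for the citation record,
         provenance: implementer-defined}
      - {name: Identifier URL, importance: 2, value_kind: url,
         description: Resolvable identifier URL, provenance: implementer-defined}
      - {name: Related Publications, importance: 3, value_kind: text,
         description: Publications describing the data,
         provenance: implementer-defined}
      - {name: Contact Email, importance: 2, value_kind: text,
         description: Dataset contact address, provenance: implementer-defined}
      - {name: Submission Date, importance: 2, value_kind: date,
         description: Date received from the producing center,
         provenance: implementer-defined}
      - {name: Comments, importance: 3, value_kind: text,
         description: Free-text notes, provenance: implementer-defined}
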