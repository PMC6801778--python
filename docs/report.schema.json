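{
  "$defs": {
    "DiffusionRow": {
      "properties": {
        "species": {
          "title": "Species",
          "type": "string"
        },
        "d": {
          "$ref": "#/$defs/ValueWithSd"
        }
      },
      "required": [
        "species",
        "d"
      ],
      "title": "DiffusionRow",
      "type": "object"
    },
    "GeometryBlock": {
      "properties": {
        "depth": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "depth_modality": {
          "title": "Depth Modality",
          "type": "integer"
        },
        "theta": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "omega": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "radius_of_gyration": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "label_fractions": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Label Fractions",
          "type": "object"
        }
      },
      "required": [
        "depth",
        "depth_modality",
        "theta",
        "omega",
        "radius_of_gyration",
        "label_fractions"
      ],
      "title": "GeometryBlock",
      "type": "object"
    },
    "MembraneBlock": {
      "properties": {
        "thickness": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "area_per_lipid": {
          "$ref": "#/$defs/ValueWithSd"
        },
        "order": {
          "$ref": "#/$defs/ValueWithSd"
        }
      },
      "required": [
        "thickness",
        "area_per_lipid",
        "order"
      ],
      "title": "MembraneBlock",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "package_version": {
          "title": "Package Version",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "config_hash",
        "package_version",
        "seed"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "SystemReport": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "membrane": {
          "anyOf": [
            {
              "$ref": "#/$defs/MembraneBlock"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "diffusion": {
          "items": {
            "$ref": "#/$defs/DiffusionRow"
          },
          "title": "Diffusion",
          "type": "array"
        },
        "geometry": {
          "anyOf": [
            {
              "$ref": "#/$defs/GeometryBlock"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "name"
      ],
      "title": "SystemReport",
      "type": "object"
    },
    "ValueWithSd": {
      "properties": {
        "value": {
          "title": "Value",
          "type": "number"
        },
        "sd": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sd"
        },
        "units": {
          "default": "",
          "title": "Units",
          "type": "string"
        }
      },
      "required": [
        "value"
      ],
      "title": "ValueWithSd",
      "type": "object"
    }
  },
  "properties": {
    "systems": {
      "items": {
        "$ref": "#/$defs/SystemReport"
      },
      "title": "Systems",
      "type": "array"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "systems",
    "provenance"
  ],
  "title": "Report",
  "type": "object"
}
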