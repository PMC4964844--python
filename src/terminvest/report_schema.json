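{
 "$defs": {
  "ComparisonRow": {
   "properties": {
    "D": {
     "title": "D",
     "type": "number"
    },
    "day": {
     "title": "Day",
     "type": "integer"
    },
    "p_perm": {
     "title": "P Perm",
     "type": "number"
    },
    "pair": {
     "title": "Pair",
     "type": "string"
    }
   },
   "required": [
    "day",
    "pair",
    "D",
    "p_perm"
   ],
   "title": "ComparisonRow",
   "type": "object"
  },
  "CytometrySection": {
   "properties": {
    "comparisons": {
     "default": [],
     "items": {
      "$ref": "#/$defs/ComparisonRow"
     },
     "title": "Comparisons",
     "type": "array"
    },
    "size_ratios": {
     "default": [],
     "items": {
      "$ref": "#/$defs/SizeRatioRow"
     },
     "title": "Size Ratios",
     "type": "array"
    },
    "skipped": {
     "default": false,
     "title": "Skipped",
     "type": "boolean"
    },
    "summaries": {
     "default": [],
     "items": {
      "$ref": "#/$defs/CytometrySummaryRow"
     },
     "title": "Summaries",
     "type": "array"
    }
   },
   "title": "CytometrySection",
   "type": "object"
  },
  "CytometrySummaryRow": {
   "properties": {
    "day": {
     "title": "Day",
     "type": "integer"
    },
    "mean_fsc": {
     "title": "Mean Fsc",
     "type": "number"
    },
    "mean_ssc": {
     "title": "Mean Ssc",
     "type": "number"
    },
    "median_fsc": {
     "title": "Median Fsc",
     "type": "number"
    },
    "n_events": {
     "title": "N Events",
     "type": "integer"
    },
    "sd_fsc": {
     "title": "Sd Fsc",
     "type": "number"
    },
    "sd_ssc": {
     "title": "Sd Ssc",
     "type": "number"
    },
    "treatment": {
     "title": "Treatment",
     "type": "string"
    }
   },
   "required": [
    "day",
    "treatment",
    "n_events",
    "mean_fsc",
    "sd_fsc",
    "median_fsc",
    "mean_ssc",
    "sd_ssc"
   ],
   "title": "CytometrySummaryRow",
   "type": "object"
  },
  "DilutionRow": {
   "properties": {
    "divisions_to_sub_unity": {
     "title": "Divisions To Sub Unity",
     "type": "integer"
    },
    "hours_to_sub_unity": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Hours To Sub Unity"
    },
    "p0": {
     "title": "P0",
     "type": "number"
    }
   },
   "required": [
    "p0",
    "divisions_to_sub_unity",
    "hours_to_sub_unity"
   ],
   "title": "DilutionRow",
   "type": "object"
  },
  "DilutionSection": {
   "properties": {
    "predictions": {
     "default": [],
     "items": {
      "$ref": "#/$defs/DilutionRow"
     },
     "title": "Predictions",
     "type": "array"
    },
    "reference_doubling_time_h": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Reference Doubling Time H"
    },
    "skipped": {
     "default": false,
     "title": "Skipped",
     "type": "boolean"
    }
   },
   "title": "DilutionSection",
   "type": "object"
  },
  "DtSummaryRow": {
   "properties": {
    "day": {
     "title": "Day",
     "type": "integer"
    },
    "mean_dt": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Mean Dt"
    },
    "n": {
     "title": "N",
     "type": "integer"
    },
    "se_dt": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Se Dt"
    },
    "treatment": {
     "title": "Treatment",
     "type": "string"
    }
   },
   "required": [
    "day",
    "treatment",
    "mean_dt",
    "n"
   ],
   "title": "DtSummaryRow",
   "type": "object"
  },
  "GrowthSection": {
   "properties": {
    "skipped": {
     "default": false,
     "title": "Skipped",
     "type": "boolean"
    },
    "summary": {
     "default": [],
     "items": {
      "$ref": "#/$defs/DtSummaryRow"
     },
     "title": "Summary",
     "type": "array"
    }
   },
   "title": "GrowthSection",
   "type": "object"
  },
  "KWRow": {
   "properties": {
    "H": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "H"
    },
    "day": {
     "title": "Day",
     "type": "integer"
    },
    "df": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "title": "Df"
    },
    "flagged": {
     "title": "Flagged",
     "type": "boolean"
    },
    "grouping": {
     "title": "Grouping",
     "type": "string"
    },
    "k": {
     "title": "K",
     "type": "integer"
    },
    "p_chisq": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "P Chisq"
    },
    "p_perm": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "P Perm"
    }
   },
   "required": [
    "day",
    "grouping",
    "k",
    "df",
    "H",
    "p_chisq",
    "p_perm",
    "flagged"
   ],
   "title": "KWRow",
   "type": "object"
  },
  "KWSection": {
   "properties": {
    "skipped": {
     "default": false,
     "title": "Skipped",
     "type": "boolean"
    },
    "tests": {
     "default": [],
     "items": {
      "$ref": "#/$defs/KWRow"
     },
     "title": "Tests",
     "type": "array"
    }
   },
   "title": "KWSection",
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
    "seed",
    "package_version"
   ],
   "title": "Provenance",
   "type": "object"
  },
  "SizeRatioRow": {
   "properties": {
    "day": {
     "title": "Day",
     "type": "integer"
    },
    "ratio_vs_control": {
     "title": "Ratio Vs Control",
     "type": "number"
    },
    "treatment": {
     "title": "Treatment",
     "type": "string"
    }
   },
   "required": [
    "day",
    "treatment",
    "ratio_vs_control"
   ],
   "title": "SizeRatioRow",
   "type": "object"
  }
 },
 "description": "Schema of ``report.json``: every section present or marked skipped.",
 "properties": {
  "cytometry": {
   "$ref": "#/$defs/CytometrySection"
  },
  "dilution": {
   "$ref": "#/$defs/DilutionSection"
  },
  "growth": {
   "$ref": "#/$defs/GrowthSection"
  },
  "kruskal_wallis": {
   "$ref": "#/$defs/KWSection"
  },
  "provenance": {
   "$ref": "#/$defs/Provenance"
  }
 },
 "required": [
  "growth",
  "kruskal_wallis",
  "cytometry",
  "dilution",
  "provenance"
 ],
 "title": "AnalysisReportModel",
 "type": "object"
}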