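source,raw_count_text,normalized_count,volume_pct
https://www.reddit.com/r/labrats/comments/1oezr1p/do_you_mix_by_pipetting_in_and_out_after_adding/,couple of times,2,80
https://www.reddit.com/r/labrats/comments/1oezr1p/do_you_mix_by_pipetting_in_and_out_after_adding/,2,2,
https://www.reddit.com/r/labrats/comments/1oezr1p/do_you_mix_by_pipetting_in_and_out_after_adding/,10,10,
https://www.reddit.com/r/labrats/comments/1oezr1p/do_you_mix_by_pipetting_in_and_out_after_adding/,20,20,
https://www.reddit.com/r/labrats/comments/1kyfmn0/how_do_you_guys_mix_your_qpcr_plates/,10,10,
https://www.reddit.com/r/labrats/comments/1kyfmn0/how_do_you_guys_mix_your_qpcr_plates/,1 - 2,1.5,
https://www.reddit.com/r/labrats/comments/1kyfmn0/how_do_you_guys_mix_your_qpcr_plates/,6,6,80
https://www.reddit.com/r/labrats/comments/1kyfmn0/how_do_you_guys_mix_your_qpcr_plates/,1 - 2,1.5,
https://www.reddit.com/r/labrats/comments/f20obn/how_do_you_guys_mix_your_96_well_plates/,2 - 3,2.5,
https://www.reddit.com/r/labrats/comments/f20obn/how_do_you_guys_mix_your_96_well_plates/,2 - 3,2.5,
https://www.reddit.com/r/labrats/comments/1giqkpt/tips_for_equal_seeding_in_a_96well_plate/,2 - 3,2.5,
https://www.reddit.com/r/labrats/comments/1l5kpq3/any_tips_of_removing_air_bubbles_forming_in_the/,10,10,50
https://www.reddit.com/r/labrats/comments/1l5kpq3/any_tips_of_removing_air_bubbles_forming_in_the/,15,15,50
https://www.anamed.com.tr/wp-content/uploads/2022/11/Reproducibility_Serial_Dilutions_V01.pdf,5,5,
https://www.cambio.co.uk/library/images/html_images/Aline/Protocol-PureGenome-Blood-gDNA-v03.pdf,10,10,
https://norgenbiotek.com/sites/default/files/resources/PI62400_6_Plant_DNA_Isolation_96_Well_Kit_Magnetic_Bead_System_Insert.pdf,10,10,
https://www.researchgate.net/post/How-should-I-pipette-2ul-of-cDNA-without-making-bubbles,2,2,
https://www.researchgate.net/post/How-should-I-pipette-2ul-of-cDNA-without-making-bubbles,5 - 10,7.5,
https://nanoporetech.com/document/ligation-sequencing-gdna-pcr-barcoding-sqk-lsk114-with-exp,10 - 20,15,
https://www.protocols.io/view/protoplast-isolation-and-transfection-in-a-96-well-ccc4ssyw.pdf,5,5,
https://documents.thermofisher.com/TFS-Assets/LSG/manuals/sequalprep_platekit_man.pdf,5,5,
https://www.integra-biosciences.com/sites/default/files/documents/498-23_Website_Application_Guide_Serial_Dilution_150623.pdf,3,3,
https://content.protocols.io/files/paffb8y37.pdf,10 - 20,15,
https://www.integra-biosciences.com/united-states/en/applications/fast-and-efficient-automated-sample-transfertubes-plates-assist-plus-pipetting-robot,3,3,
https://www.integra-biosciences.com/global/en/blog/article/how-do-serial-dilutions-including-calculations,5,5,
https://www.thermofisher.com/us/en/home/references/protocols/cell-and-tissue-analysis/elisa-protocol/elisasample-preparation-protocols/sample-preparation-adherent-suspension-cells.html,5 - 6,5.5,
https://www.magbiogenomics.com/pub/media/productattach/h/i/highprep_plasmid_dna_-_protocol.pdf,10,10,
https://www.pacb.com/wp-content/uploads/Procedure-checklist-Generating-PureTarget-libraries-with-PureTarget-kit-96-automation-protocol.pdf,5,5,
https://www.agilent.com/cs/library/usermanuals/public/5991-7930EN.pdf,3 - 5,4,
https://www.beckman.com/reagents/genomic/cleanup-and-size-selection/pcr/ampure-xp-protocol,10,10,
https://www.sopachem.com/lifesciences/wp-content/uploads/2018/10/Instruction-Guide-for-use-of-Syntrix-P.pdf,10 - 20,15,
https://genome.med.harvard.edu/documents/sequencing/Agencourt_CosMCPrepProtocol.pdf,10,10,
https://www.neb.com/en-us/protocols/2018/06/04/protocol-for-nebnext-direct-custom-ready-panels-nebe6631,10,10,
https://www.bdbiosciences.com/en-eu/resources/protocols/96-deep-well-staining-cytokine,3,3,
https://www.protocols.io/view/protoplast-isolation-and-transfection-in-a-96-well-yxmvmn1d6g3p/v1,5,5,
https://protocols.opentrons.com/categories/Sample%20Prep/Serial%20Dilution,12,12,
https://www.andrewalliance.com/wp-content/uploads/2022/02/618.002_IQ-OQ-Pipette-v7-NV-20220225.pdf,2,2,
https://www.sciencedirect.com/science/article/pii/S2472630322020659,3,3,
https://documents.thermofisher.com/TFS-Assets/LSG/manuals/100008679.pdf,6,6,
https://www.jove.com/v/64298/fast-colony-forming-unit-counting-96-well-plate-format-applied-to,10,10,
https://www.jove.com/t/57713/diagonal-method-to-measure-synergy-among-any-number-of-drugs,5,5,
https://www.nature.com/articles/s41598-018-30305-z,6,6,
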