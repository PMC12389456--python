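# 22-group food taxonomy for the heart-protective diet score (HPDS).
# Each group carries a scoring direction (+1 heart-protective, -1 discouraged),
# a serve size in grams (drinks in mL treated 1:1 as grams), the number of
# underlying 24 h recall instrument items it covers (declared_item_count),
# and the item names. Item identifiers are slugified from names at load time.
#
# Two groups (nuts_seeds, legumes_beans) declare more instrument items than
# named entries; the source table prints an abbreviated item list for them.
# The loader records this as a warning, not an error.
ignore_items:
  - alcoholic beverages
  - highly processed vegetarian alternatives
  - vegetable fats
  - salted nuts
groups:
  - name: Wholegrains
    direction: 1
    serve_size_g: 60
    declared_item_count: 14
    items:
      - porridge
      - muesli
      - oat crunch
      - bran cereal
      - non-white bread
      - seeded or other bread
      - crispbread
      - whole-wheat cereal
      - other cereal
      - oatcakes
      - wholemeal pasta
      - brown rice
      - couscous
      - other cooked grains
  - name: Fruits
    direction: 1
    serve_size_g: 80
    declared_item_count: 20
    items:
      - avocado
      - mixed fruit
      - apple
      - banana
      - berries
      - cherries
      - grapefruit
      - grapes
      - mango
      - melon
      - orange
      - orange-like small fruits
      - peach or nectarine
      - pear
      - pineapple
      - plum
      - other fruits
      - stewed or cooked fruit
      - prunes
      - other dried fruit
  - name: Non-starchy Vegetables
    direction: 1
    serve_size_g: 80
    declared_item_count: 26
    items:
      - mixed vegetables
      - vegetable pieces
      - coleslaw
      - side salad
      - beetroot
      - broccoli
      - cabbage or kale
      - carrots
      - cauliflower
      - celery
      - courgette
      - cucumber
      - garlic
      - leeks
      - lettuce
      - mushrooms
      - onion
      - parsnip
      - sweet peppers
      - spinach
      - sprouts
      - fresh tomatoes
      - cooked or tinned tomatoes
      - turnip or swede
      - watercress
      - other vegetable intake
  - name: Starchy Vegetables
    direction: 1
    serve_size_g: 75
    declared_item_count: 3
    items:
      - butternut squash
      - sweetcorn
      - sweet potato
  - name: Nuts and Seeds
    direction: 1
    serve_size_g: 30
    declared_item_count: 5
    items:
      - unsalted peanuts
      - unsalted nuts
      - seeds
  - name: Legumes and Beans, Other Vegetarian Protein Alternatives
    direction: 1
    serve_size_g: 80
    declared_item_count: 9
    items:
      - beans
      - other beans or lentils
      - broad beans
      - green beans
      - peas
      - tofu
      - quorn
  - name: Uncoated Fish and Seafood
    direction: 1
    serve_size_g: 140
    declared_item_count: 7
    items:
      - tinned tuna
      - oily fish
      - white fish
      - prawns
      - lobster or crab
      - shellfish
      - other fish intake
  - name: Eggs
    direction: 1
    serve_size_g: 120
    declared_item_count: 5
    items:
      - whole eggs
      - omelettes or scrambled eggs
      - eggs in sandwiches
      - scotch egg
      - other egg dishes
  - name: Reduced-fat Milk and Dairy Products
    direction: 1
    serve_size_g: 250
    declared_item_count: 4
    items:
      - milk
      - low fat hard cheese
      - low fat cheese spread
      - cottage cheese
  - name: Tea, Coffee and Other Low-calorie Drinks
    direction: 1
    serve_size_g: 250
    declared_item_count: 11
    items:
      - instant coffee
      - filtered coffee
      - cappuccino
      - latte
      - espresso
      - other coffee drinks
      - standard tea
      - rooibos tea
      - green tea
      - herbal tea
      - other tea
  - name: Homemade Soup
    direction: 1
    serve_size_g: 250
    declared_item_count: 1
    items:
      - homemade soup
  - name: Refined Grains and Cereals
    direction: -1
    serve_size_g: 60
    declared_item_count: 12
    items:
      - sweetened cereal
      - plain cereal
      - white sliced bread
      - white bread
      - white bap
      - white bread roll
      - naan bread
      - garlic bread
      - white pasta
      - white rice
      - pancake
      - snackpot
  - name: Potatoes
    direction: -1
    serve_size_g: 75
    declared_item_count: 4
    items:
      - fried potatoes
      - boiled or baked potatoes
      - mashed potatoes
      - crisps
  - name: Meat, Poultry and Processed Meat
    direction: -1
    serve_size_g: 70
    declared_item_count: 10
    items:
      - sausage
      - beef
      - pork
      - lamb
      - crumbed or deep-fried poultry
      - poultry
      - bacon
      - ham
      - liver
      - other meat intake
  - name: Coated Fish and Seafood
    direction: -1
    serve_size_g: 140
    declared_item_count: 2
    items:
      - breaded fish
      - battered fish
  - name: Full-fat Milk and Dairy Products
    direction: -1
    serve_size_g: 250
    declared_item_count: 10
    items:
      - flavored milk
      - yogurt
      - hard cheese
      - soft cheese
      - blue cheese
      - cheese spread
      - feta cheese
      - mozzarella cheese
      - goats cheese
      - other cheese
  - name: Processed Soup
    direction: -1
    serve_size_g: 250
    declared_item_count: 2
    items:
      - powdered or instant soup
      - canned soup
  - name: Sugar, Sweets and Desserts, Cookies and Pastries
    direction: -1
    serve_size_g: 40
    declared_item_count: 23
    items:
      - added sugar
      - ice-cream
      - milk-based pudding
      - other milk-based pudding
      - soya dessert
      - fruitcake
      - cake
      - doughnuts
      - sponge pudding
      - cheesecake
      - other dessert
      - chocolate bar
      - white chocolate
      - milk chocolate
      - dark chocolate
      - chocolate-covered raisin
      - chocolate sweet
      - diet sweets
      - chocolate-covered biscuits
      - chocolate biscuits
      - sweet biscuits
      - cereal bar
      - other sweets
  - name: Savory Snacks
    direction: -1
    serve_size_g: 30
    declared_item_count: 2
    items:
      - savory or cheesy biscuits
      - other savory snacks
  - name: Sugary Drinks
    direction: -1
    serve_size_g: 150
    declared_item_count: 3
    items:
      - low-calorie hot chocolate
      - hot chocolate
      - other non-alcoholic drinks
  - name: Artificial Sweetener
    direction: -1
    serve_size_g: 4
    declared_item_count: 1
    items:
      - artificial sweetener
  - name: Unhealthy Fat
    direction: -1
    serve_size_g: 10
    declared_item_count: 2
    items:
      - butter or margarine on bread
      - bread slices with butter or margarine
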